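# Capitalized place-name distractors for the synthetic corpus generator.
# Several deliberately carry Latin-looking endings (-a, -ia, -um) so that
# structural features alone cannot separate them from genus names.
Atlanta
Georgia
Savannah
Augusta
Arizona
Alabama
Montana
Virginia
Carolina
Florida
Columbia
Pasadena
Tacoma
Wichita
Sonora
Verona
Cremona
Bologna
Ravenna
Catania
Valencia
Granada
Cordoba
Toledo
Lisbon
Boston
Chicago
Denver
Portland
Halifax
Winnipeg
Ottawa
Havana
Bogota
Lima
Cusco
Santiago
Cordillera
Patagonia
Tasmania
Queensland
Canberra
Nairobi
Mombasa
Kampala
Luanda
Tripoli
Alexandria
Smyrna
Antioch
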