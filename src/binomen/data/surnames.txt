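# Capitalized surname distractors for the synthetic corpus generator.
Smith
Johnson
Walker
Thompson
Harris
Martin
Clarke
Lewis
Turner
Baker
Carter
Mitchell
Roberts
Campbell
Stewart
Morris
Murray
Watson
Graham
Fraser
Sutherland
Drummond
Livingstone
Darwin
Hooker
Wallace
Bates
Spruce
Banks
Solander
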