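# Common English words removed from candidate names during pre-filtering.
# One word per line, matching is case-insensitive.
the
a
an
and
or
but
nor
so
yet
of
in
on
at
by
with
from
into
near
for
to
as
is
are
was
were
be
been
being
has
have
had
can
could
may
might
will
would
shall
should
must
do
does
did
not
no
yes
it
its
he
she
they
them
their
his
her
we
our
you
your
this
that
these
those
there
here
where
when
which
who
whom
whose
what
how
why
all
any
both
each
few
more
most
other
some
such
only
own
same
than
too
very
just
also
then
once
during
before
after
above
below
between
under
over
again
further
about
against
among
through
while
because
until
unless
since
however
therefore
thus
hence
several
many
much
new
old
large
small
long
short
high
low
first
second
third
last
next
early
late
good
great
major
minor
general
common
main
city
town
state
country
region
north
south
east
west
summer
winter
spring
autumn
year
years
day
days
time
times
report
reports
record
records
result
results
survey
surveys
method
methods
sample
samples
specimen
specimens
species
genus
genera
family
field
data
value
values
number
numbers
figure
table
detail
details
site
sites
area
areas
map
maps
team
material
museum
collection
expedition
weather
travellers
professor
mister
madam
archived
published
deposited
measured
recorded
obtained
prepared
described
describes
examined
collected
stored
visited
admired
lies
occurs
comprises
differs
adjacent
national
detailed
marine
pelagic
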