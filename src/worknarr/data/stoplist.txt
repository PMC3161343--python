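# Default English stop list (one word per line; '#' starts a comment).
# Entries are stemmed on load, so inflected forms are covered.
# Words naming body parts, injury mechanisms or injurious objects are
# deliberately rescued from this list by stop_overrides.txt.
a
about
above
after
again
against
all
am
an
and
any
are
as
at
back
be
because
been
before
being
below
between
both
but
by
came
can
could
did
do
does
doing
down
during
each
few
for
from
further
get
got
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
i
if
in
into
is
it
its
itself
just
me
more
most
my
myself
no
nor
not
now
of
off
on
once
only
onto
or
other
our
ours
ourselves
out
over
own
said
same
saw
she
should
so
some
such
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
to
today
too
under
until
up
upon
very
was
we
went
were
what
when
where
which
while
who
whom
why
will
with
would
yesterday
you
your
yours
yourself
yourselves
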