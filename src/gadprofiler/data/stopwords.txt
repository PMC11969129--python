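i
me
my
myself
we
our
ours
ourselves
you
your
yours
yourself
yourselves
he
him
his
himself
she
her
hers
herself
it
its
itself
they
them
their
theirs
themselves
what
which
who
whom
this
that
these
those
am
is
are
was
were
be
been
being
have
has
had
having
do
does
did
doing
a
an
the
and
or
nor
as
of
at
by
for
with
about
against
between
into
through
during
before
after
above
below
to
from
up
down
in
out
on
off
over
under
again
further
then
once
here
there
when
where
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
no
not
only
own
same
so
than
too
very
s
t
can
will
just
don
don't
now
im
i'm
i've
i'll
i'd
you're
you've
it's
isn't
wasn't
aren't
weren't
haven't
hasn't
hadn't
doesn't
didn't
won't
wouldn't
can't
cannot
couldn't
shouldn't
that's
there's
what's
let's
gonna
gotta
u
ur
rt
via
amp
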