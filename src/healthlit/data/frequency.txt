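# Frequency-ranked lemma list (descending), starter subset.
the
be
to
of
and
a
in
that
have
it
for
not
on
with
he
as
you
do
at
this
but
his
by
from
they
we
say
her
she
or
an
will
my
one
all
would
there
their
what
so
up
out
if
about
who
get
which
go
me
when
make
can
like
time
no
just
him
know
take
person
into
year
your
good
some
could
them
see
other
than
then
now
look
only
come
its
over
think
also
back
after
use
two
how
our
work
first
well
way
even
new
want
because
any
these
give
day
most
us
is
was
were
are
am
been
being
people
may
find
here
thing
many
tell
very
still
should
must
try
ask
need
feel
become
leave
put
mean
keep
let
begin
seem
help
talk
turn
start
show
hear
play
run
move
live
believe
hold
bring
happen
write
sit
stand
lose
pay
meet
include
continue
set
learn
change
lead
understand
watch
follow
stop
speak
read
spend
grow
open
walk
win
offer
remember
love
consider
appear
buy
wait
serve
die
send
build
stay
fall
cut
reach
kill
raise
pass
sell
decide
return
explain
hope
develop
carry
break
receive
agree
support
hit
produce
eat
cover
catch
draw
choose
point
listen
drink
rest
sleep
check
plan
care
team
home
book
note
water
food
air
hand
eye
head
face
body
arm
leg
foot
heart
blood
skin
hair
mouth
tooth
ear
nose
child
man
woman
family
friend
mother
father
baby
life
world
school
house
room
door
car
road
city
country
place
area
side
part
end
kind
name
number
week
month
hour
minute
night
morning
today
tomorrow
yesterday
word
question
answer
problem
idea
fact
case
group
company
service
system
program
money
business
job
issue
result
reason
story
news
level
order
line
form
rule
law
right
power
war
peace
doctor
nurse
hospital
medicine
medication
health
healthy
patient
pain
test
treatment
therapy
surgery
vaccine
virus
infection
symptom
disease
condition
appointment
emergency
important
information
exercise
diet
tablet
dose
cancer
diabetes
mental
chronic
dementia
little
big
small
large
long
short
high
low
old
young
early
late
few
much
more
less
own
same
different
able
sure
clear
easy
hard
free
full
real
whole
best
better
bad
worse
great
nice
fine
warm
cool
hot
cold
fever
cough
flu
ache
stomach
liver
kidney
lung
every
each
both
another
next
last
several
enough
again
always
never
often
sometimes
usually
really
finally
together
please
thank
yes
almost
around
away
down
off
above
below
near
far
between
through
during
before
since
until
while
against
without
within
across
toward
among
victim
cease
obtain
assist
prior
possible
available
community
activity
ability
recovery
regular
immediate
experience
education
operation
advice
visit
call
phone
letter
page
list
step
guide
benefit
risk
safe
safety
danger
harm
injury
allergy
energy
weight
height
age
sign
record
chart
score
grade
pressure
evening
afternoon
breakfast
lunch
dinner
shower
toilet
stair
chemist
pharmacy
pharmacist
clinic
ward
bandage
wound
swelling
rash
itch
bruise
pill
cream
drop
spray
injection
needle
thermometer
reading
smoking
breathing
temperature
blood-pressure
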