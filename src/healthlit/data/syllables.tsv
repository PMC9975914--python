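# Syllable dictionary: word<TAB>syllables. Starter subset; the vowel-group
# heuristic covers words not listed here.
the	1
be	1
to	1
of	1
and	1
a	1
in	1
that	1
have	1
it	1
for	1
not	1
on	1
with	1
as	1
you	1
do	1
at	1
this	1
but	1
his	1
by	1
from	1
they	1
we	1
say	1
her	1
she	1
or	1
an	1
will	1
my	1
one	1
all	1
would	1
there	1
their	1
what	1
so	1
up	1
out	1
if	1
about	2
who	1
get	1
which	1
go	1
me	1
when	1
make	1
can	1
like	1
time	1
no	1
just	1
him	1
know	1
take	1
person	2
people	2
into	2
year	1
your	1
good	1
some	1
could	1
them	1
see	1
other	2
than	1
then	1
now	1
look	1
only	2
come	1
its	1
over	2
think	1
also	2
back	1
after	2
use	1
two	1
how	1
our	1
work	1
first	1
well	1
way	1
even	2
new	1
want	1
because	2
any	2
these	2
give	1
day	1
most	1
us	1
was	1
were	1
been	1
being	2
are	1
is	1
am	1
doctor	2
nurse	1
blood	1
test	1
hospital	3
medicine	3
medication	4
health	1
healthy	2
patient	2
cancer	2
diabetes	4
dementia	3
pain	1
chronic	2
mental	2
treatment	2
therapy	3
surgery	3
vaccine	2
virus	2
infection	3
symptom	2
disease	2
condition	3
appointment	3
emergency	4
important	3
information	4
consultation	4
exercise	3
diet	2
water	2
sleep	1
smoke	1
heart	1
lung	1
kidney	2
liver	2
stomach	2
ache	1
fever	2
cough	1
cold	1
flu	1
tablet	2
dose	1
check	1
checked	1
science	2
area	3
idea	3
quiet	2
question	2
family	3
every	2
very	2
many	2
body	2
energy	3
allergy	3
injury	3
delivered	3
given	2
ordered	2
gobbledygook	4
together	3
remember	3
sufferer	3
victim	2
sedge	1
torpor	2
quoll	1
cease	1
obtain	2
assist	2
prior	2
stop	1
before	2
help	1
little	2
people-centred	4
everyone	3
something	2
anything	3
usually	4
really	2
finally	3
different	3
possible	3
available	4
understand	3
community	4
activity	4
ability	4
recovery	4
regularly	4
immediately	5
experience	4
education	4
operation	4
organisation	5
organization	5
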