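# Ordinary greenhouse tomato: leaves and flowers develop on separate
# branches (type 2 grows leaves only, type 3 grows flower stalks only).
#
# Main stem control A(i, j): one internode per stage; i walks the branch
# choice string, j counts internodes produced.  Each new lateral branch
# sprouts higher than all previous ones; '/' spreads successive branches
# around the stem, '&' pitches them away from it.
A(i,j) : choice(i)!=4 && choice(i)!=5 && choice(i)!=-1 -> F(0) / [& B(choice(i),0)] A(i+1,j+1)
A(i,j) : choice(i)==4 -> F(0) [Y(4,0) y(0)]
A(i,j) : choice(i)==5 -> F(0) [Y(5,0) y(0)]
A(i,j) : choice(i)==-1 -> F(0)

# Lateral branch control: dispatch by branch form.
B(t,age) : t==1 -> C(0)
B(t,age) : t!=1 -> D(t,0)

# Type 1: a short branch / compound leaf that cannot fully develop.  Its
# final rewrite plants a mature leaf L(r), which bifurcates next stage.
C(age) : age==0 -> S(0) C(1)
C(age) : age==1 -> S(0) C(2)
C(age) : age==2 -> S(0) [+ L(r)]

# Full-fledged branches.  Type 2 bears leaves along non-flowering
# internodes f and a terminal leaf l; type 3 bears flower stalks P along
# flowering internodes h.
D(t,age) : t==2 && age==0 -> f(0) [# L(0)] D(2,1)
D(t,age) : t==2 && age==1 -> f(0) [# L(0)] D(2,2)
D(t,age) : t==2 && age==2 -> f(0) [# l(0)]
D(t,age) : t==3 && age==0 -> h(0) [& P(0)] D(3,1)
D(t,age) : t==3 && age==1 -> h(0) [& P(0)] D(3,2)
D(t,age) : t==3 && age==2 -> h(0) [& P(0)]

# Terminal branch atop the main stem: type 4 grows leaves only, type 5
# grows flower stalks.
Y(t,age) : t==4 && age==0 -> Y(4,1) [+ L(0)] [- L(0)]
Y(t,age) : t==5 && age==0 -> Y(5,1) [+ P(0)] [- P(0)]

# A flower stalk opens one flower; a withered flower is replaced by a
# young fruit which then ripens (ages to maturity, then state r).
P(age) : age==1 -> P(2) H(0)
H(age) : age==2 -> G(0)

# Leaf bifurcation: a mature leaf splits into two leaves.  The successor
# deliberately closes and reopens a bracket so that the fragment [+L(r)]
# becomes [+L(3)][-L(0)].
L(age) : age==r -> L(3) ] [ - L(0)
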