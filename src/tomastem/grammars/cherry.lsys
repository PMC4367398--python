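# Cherry tomato: the flowering branch (type 3) carries leaves and flower
# stalks together on the same branch, unlike the ordinary variety where
# they appear on separate branches.  All other rules are shared.
A(i,j) : choice(i)!=4 && choice(i)!=5 && choice(i)!=-1 -> F(0) / [& B(choice(i),0)] A(i+1,j+1)
A(i,j) : choice(i)==4 -> F(0) [Y(4,0) y(0)]
A(i,j) : choice(i)==5 -> F(0) [Y(5,0) y(0)]
A(i,j) : choice(i)==-1 -> F(0)

B(t,age) : t==1 -> C(0)
B(t,age) : t!=1 -> D(t,0)

C(age) : age==0 -> S(0) C(1)
C(age) : age==1 -> S(0) C(2)
C(age) : age==2 -> S(0) [+ L(r)]

D(t,age) : t==2 && age==0 -> f(0) [# L(0)] D(2,1)
D(t,age) : t==2 && age==1 -> f(0) [# L(0)] D(2,2)
D(t,age) : t==2 && age==2 -> f(0) [# l(0)]
# leaves and flowers on the same branch:
D(t,age) : t==3 && age==0 -> h(0) [# L(0)] [& P(0)] D(3,1)
D(t,age) : t==3 && age==1 -> h(0) [# L(0)] [& P(0)] D(3,2)
D(t,age) : t==3 && age==2 -> h(0) [& P(0)] [# l(0)]

Y(t,age) : t==4 && age==0 -> Y(4,1) [+ L(0)] [- L(0)]
Y(t,age) : t==5 && age==0 -> Y(5,1) [+ P(0)] [- P(0)]

P(age) : age==1 -> P(2) H(0)
H(age) : age==2 -> G(0)

L(age) : age==r -> L(3) ] [ - L(0)
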