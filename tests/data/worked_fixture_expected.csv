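genotype,DC,GMP,MP,SSI,STI,TOL
w1,0.25,200,250,1.18955512572534,0.152290303390839,300
w2,1,300,300,0,0.342653182629387,0
w3,0.01,50,252.5,1.57021276595745,0.00951814396192742,495
w4,0.5,565.685424949238,600,0.793036750483559,1.21832242712671,400
w5,0.75,173.205080756888,175,0.39651837524178,0.114217727543129,50
w6,0.4,379.473319220205,420,0.951644100580271,0.54824509220702,360
w7,0.2,447.213595499958,600,1.26885880077369,0.761451516954194,800
w8,0.4,189.736659610103,210,0.951644100580271,0.137061273051755,180
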