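scale,item,w
HGS,ears,0.567
HGS,orb,0.794
HGS,ten,0.470
HGS,chew,0.421
HGS,mouth,0.418
HGS,nost,0.575
EQUUS_FAP,head,0.383
EQUUS_FAP,eye,0.433
EQUUS_FAP,focus,0.819
EQUUS_FAP,nost,0.405
EQUUS_FAP,mouth,0.316
EQUUS_FAP,tone,0.329
EQUUS_FAP,fleya,0.751
EQUUS_FAP,teeth,0.333
EQUUS_FAP,ears,0.376
EPS,pf,0.428
EPS,gross,0.753
EPS,act,0.722
EPS,loc,0.605
EPS,pos,0.743
EPS,head,0.409
EPS,att,0.333
EPS,int,0.775
EPS,food,0.881
CPS,kick,0.333
CPS,paw,0.763
CPS,head,0.538
CPS,app,0.646
CPS,pos,0.741
CPS,app2,0.837
CPS,sweat,0.920
CPS,int,0.333
CPS,palp,0.844
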