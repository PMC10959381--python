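class_name,x,y,z,group,side
AVAL,0.50,0.00,0.25,backward,L
AVAR,0.50,0.00,-0.25,backward,R
AVEL,0.00,-0.05,0.25,backward,L
AVER,0.00,-0.05,-0.25,backward,R
AIBL,-0.50,0.05,0.25,backward,L
AIBR,-0.50,0.05,-0.25,backward,R
RIML,-0.75,0.15,0.30,backward,L
RIMR,-0.75,0.15,-0.30,backward,R
VA01,-1.90,-0.10,0.05,backward,none
DA01,-1.75,0.10,-0.05,backward,none
AVBL,-0.35,0.20,0.18,forward,L
AVBR,-0.35,0.20,-0.18,forward,R
RIBL,-0.55,0.25,0.28,forward,L
RIBR,-0.55,0.25,-0.28,forward,R
RMEL,1.10,0.05,0.22,forward,L
RMER,1.10,0.05,-0.22,forward,R
RMED,1.05,0.30,0.00,forward,none
RMEV,1.05,-0.25,0.00,forward,none
RID,0.30,0.40,0.00,forward,none
RIS,-0.65,-0.20,0.05,forward,none
DB01,-1.60,0.15,0.08,forward,none
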