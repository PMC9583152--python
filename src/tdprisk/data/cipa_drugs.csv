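drug,cmax_nM,risk,split
Quinidine,3237,high,train
Sotalol,14690,high,train
Dofetilide,2,high,train
Bepridil,33,high,train
Cisapride,2.6,intermediate,train
Terfenadine,4,intermediate,train
Chlorpromazine,38,intermediate,train
Ondansetron,139,intermediate,train
Verapamil,81,low,train
Ranolazine,1948.20,low,train
Diltiazem,122,low,train
Mexiletine,4129,low,train
Disopyramide,742,high,test
Ibutilide,100,high,test
Vandetanib,255,high,test
Azimilide,70,high,test
Clarithromycin,1206,intermediate,test
Clozapine,71,intermediate,test
Domperidone,19,intermediate,test
Droperidol,6.3,intermediate,test
Pimozide,0.43,intermediate,test
Astemizole,0.26,intermediate,test
Risperidone,1.81,intermediate,test
Metoprolol,1800,low,test
Nifedipine,7.7,low,test
Nitrendipine,3.02,low,test
Tamoxifen,21,low,test
Loratadine,0.45,low,test
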