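participant_id,text,job_performance,personality_looks,life_threat,other
S01,"Lose weight, fatty!",0,0,0,1
S02,"Fool, idiot!",1,0,0,0
S03,"Ugly, smelly, please die.",0,1,1,0
S04,"Don't you understand Japanese? Are you mute or deaf?",0,0,0,1
S05,"Go home, you idiot!",1,0,0,0
S06,"Please die.",0,0,1,0
S07,"You idiot. Hey, I'll kill you. Die, you son of a bitch!",1,0,1,0
S08,"Resign your job! I'll tell the owner to make you quit!",1,0,0,0
S09,"Useless!",1,0,0,0
S10,"Deadhead, we don't need you!",0,0,0,1
S11,"Resign by yourself. You're an eyesore!",1,0,0,0
S12,"I hope you quit.",1,0,0,0
S13,"Don't come to work anymore!",0,0,0,1
S14,"I know I shouldn't discriminate, but you're the one who didn't have children, so you can't think about others.",0,0,0,1
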