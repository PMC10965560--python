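arousal,valence,dominance,emotion,descartes
0,0,0,Neutral,0
0,0,1,Other,0
0,0,-1,Other,0
0,1,0,Desire,1
0,1,1,Other,0
0,1,-1,Satisfaction,0
0,-1,0,Other,0
0,-1,1,Pessimism,0
0,-1,-1,Other,0
1,0,0,Admiration,1
1,0,1,Other,0
1,0,-1,Other,0
1,1,0,Joy,1
1,1,1,Generosity,0
1,1,-1,Love,1
1,-1,0,Distressed,0
1,-1,1,Anxious,0
1,-1,-1,Hate,1
-1,0,0,Other,0
-1,0,1,Calm,0
-1,0,-1,Other,0
-1,1,0,Relaxed,0
-1,1,1,Overconfident,0
-1,1,-1,Relief,0
-1,-1,0,Sadness,1
-1,-1,1,Rejected,0
-1,-1,-1,Other,0
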