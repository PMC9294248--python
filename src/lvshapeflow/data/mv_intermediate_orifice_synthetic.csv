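x,y
0.940000,0.000000
0.939551,0.123694
0.936964,0.251059
0.928742,0.384698
0.909782,0.525263
0.874330,0.670897
0.817107,0.817107
0.734408,0.957099
0.625000,1.082532
0.490669,1.184580
0.336317,1.255150
0.169576,1.288060
0.000000,1.280000
-0.162080,1.231120
-0.306842,1.145150
-0.426233,1.029017
-0.515000,0.892006
-0.571348,0.744595
-0.597107,0.597107
-0.597389,0.458393
-0.579782,0.334737
-0.553179,0.229134
-0.526438,0.141059
-0.507048,0.066754
-0.500000,0.000000
-0.507048,-0.066754
-0.526438,-0.141059
-0.553179,-0.229134
-0.579782,-0.334737
-0.597389,-0.458393
-0.597107,-0.597107
-0.571348,-0.744595
-0.515000,-0.892006
-0.426233,-1.029017
-0.306842,-1.145150
-0.162080,-1.231120
-0.000000,-1.280000
0.169576,-1.288060
0.336317,-1.255150
0.490669,-1.184580
0.625000,-1.082532
0.734408,-0.957099
0.817107,-0.817107
0.874330,-0.670897
0.909782,-0.525263
0.928742,-0.384698
0.936964,-0.251059
0.939551,-0.123694
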