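stratum,observed_q,true_q,count
0,1,1,710
0,1,2,590
0,1,3,405
0,1,4,325
0,1,5,205
0,2,1,455
0,2,2,615
0,2,3,560
0,2,4,490
0,2,5,395
0,3,1,415
0,3,2,570
0,3,3,560
0,3,4,540
0,3,5,470
0,4,1,310
0,4,2,465
0,4,3,570
0,4,4,595
0,4,5,635
0,5,1,220
0,5,2,370
0,5,3,455
0,5,4,560
0,5,5,950
1,1,1,730
1,1,2,540
1,1,3,330
1,1,4,230
1,1,5,150
1,2,1,500
1,2,2,575
1,2,3,385
1,2,4,315
1,2,5,195
1,3,1,380
1,3,2,490
1,3,3,370
1,3,4,330
1,3,5,260
1,4,1,285
1,4,2,380
1,4,3,345
1,4,4,345
1,4,5,305
1,5,1,230
1,5,2,330
1,5,3,315
1,5,4,335
1,5,5,470
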