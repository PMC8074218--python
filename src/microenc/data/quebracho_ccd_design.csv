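run_id,point_class,coded_core_shell,coded_md_ga,actual_core_shell,actual_md_ga
1,factorial,-1,-1,0.5,2
2,factorial,1,-1,1.5,2
3,factorial,-1,1,0.5,3
4,factorial,1,1,1.5,3
5,axial,-1.414,0,0.29,2.5
6,axial,1.414,0,1.7,2.5
7,axial,0,-1.414,1,1.5
8,axial,0,1.414,1,3.5
9,center,0,0,1,2.5
10,center,0,0,1,2.5
11,center,0,0,1,2.5
12,center,0,0,1,2.5
13,center,0,0,1,2.5
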