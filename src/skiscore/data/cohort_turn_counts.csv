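participant,experience,group,carving_long,carving_medium,carving_short,drifting_long,drifting_medium,drifting_short
1,WC,ref,10,42,29,9,25,1
3,WC,test,3,4,0,0,0,0
4,Instructor,test,0,0,0,0,0,34
5,Instructor,test,0,0,0,0,0,37
6,FIS,test,0,0,0,0,18,10
7,Instructor,test,0,0,0,0,1,23
8,Instructor,test,0,0,12,0,0,22
9,Instructor,test,0,0,5,0,2,18
11,Instructor,test,0,0,0,0,2,15
12,Instructor,test,1,10,7,0,0,17
14,Instructor,test,15,16,2,8,11,2
15,FIS,test,4,42,22,5,17,47
16,Instructor,test,0,33,4,7,43,35
17,Instructor,ref,2,73,12,14,24,3
19,Instructor,ref,8,18,30,6,12,5
20,Instructor,test,5,54,25,12,22,45
21,FIS,test,13,21,14,6,16,20
23,WC,ref,10,59,59,20,6,27
24,WC,ref,11,43,0,21,9,0
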