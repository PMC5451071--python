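donor,DRB1-1,DRB1-2,DRB3-1,DRB3-2,DRB4-1,DRB4-2,DRB5-1,DRB5-2,DQB1-1,DQB1-2,DQA1-1,DQA1-2,DPB1-1,DPB1-2,DPA1-1,DPA1-2
1,*13:02,*15:01,*03:01,-,-,-,*01:01,-,*06:02,*06:04,*03:01,*04:01,*01:01,*01:02,*01:03,-
2,*03:01,*04:04,*01:01,-,*01:01,-,-,-,*02:01,*03:02,*04:01,*04:02,*03:01,*05:01,*01:03,-
3,*12:01,*15:01,*02:02,-,-,-,*01:01,-,*03:01,*06:02,*04:02,*05:01,*01:01,*05:01,*01:03,*02:02
4,*11:01,*15:01,*02:02,-,-,-,*01:01,-,*03:01,*06:02,*04:02,*05:01,*01:01,*05:01,*01:03,-
5,*04:01,*04:04,-,-,*01:01,-,-,-,*03:02,-,*03:01,-,*03:01,-,*01:03,-
6,*13:02,*14:01,*02:02,*03:01,-,-,-,-,*05:03,*06:04,*04:01,-,*01:01,*01:02,*01:03,-
7,*13:01,*14:01,*01:01,*02:02,-,-,-,-,*05:03,*06:03,*04:01,*04:02,*01:01,*01:03,*01:03,-
8,*03:01,*04:04,*01:01,-,*01:01,-,-,-,*02:01,*03:02,*01:01,*03:01,*03:01,*05:01,*01:03,*02:01
9,*03:01,*07:01,*02:02,-,*01:03,-,-,-,*02:01,*03:03,*04:01,-,*02:01,*05:01,*01:03,-
10,*07:01,*13:01,*01:01,-,*01:01,-,-,-,*02:02,*06:03,*02:01,-,*01:03,*02:01,*01:03,-
11,*01:01,*13:02,*03:01,-,-,-,-,-,*05:01,*06:04,*06:01,*09:01,*01:01,*01:02,*01:03,*02:01
12,*04:04,*04:07,-,-,*01:01,-,-,-,*03:01,*03:02,*03:01,*19:01,*03:01,-,*01:03,*02:02
13,*07:01,*10:01,-,-,*01:01,-,-,-,*02:02,*05:01,*02:01,*11:01,*01:01,*02:01,*01:03,*02:01
14,*03:01,*13:02,*01:01,*03:01,-,-,-,-,*02:01,*06:04,*04:01,-,*01:02,*05:01,*01:03,-
15,*01:01,*07:01,-,-,*01:03,-,-,-,*03:03,*05:01,*04:01,*10:01,*01:01,*02:01,*01:03,*02:01
16,*03:01,*04:01,*01:01,-,*01:01,-,-,-,*02:01,*03:02,*04:01,-,*03:01,*05:01,*01:03,-
17,*15:01,-,-,-,-,-,*01:01,-,*06:02,-,*03:01,*15:01,*01:01,-,*01:03,*01:04
18,*11:01,*13:01,*01:01,*02:02,-,-,-,-,*03:01,*06:03,*02:01,*04:02,*01:03,*05:01,*01:03,-
19,*07:01,*15:01,-,-,*01:03,-,*01:01,-,*03:03,*06:02,*04:01,-,*01:02,*02:01,*01:03,-
20,*01:01,*01:02,-,-,-,-,-,-,*05:01,-,*02:01,*03:01,*01:01,-,*01:03,-
21,*01:01,*07:01,-,-,*01:01,-,-,-,*02:02,*05:01,*04:01,*11:01,*01:01,*02:01,*01:03,*02:01
22,*04:01,*04:04,-,-,*01:01,-,-,-,*03:02,-,*02:01,*04:02,*03:01,-,*01:03,-
23,*01:01,*15:01,-,-,-,-,*01:01,-,*05:01,*06:02,*02:01,*04:01,*01:01,*01:02,*01:03,-
24,*04:04,*15:01,-,-,*01:01,-,*01:01,-,*03:02,*06:02,*04:01,-,*01:02,*03:01,*01:03,-
25,*04:04,*14:01,*02:02,-,*01:01,-,-,-,*03:02,*05:03,*03:01,*04:01,*01:01,*03:01,*01:03,-
26,*04:01,*13:02,*03:01,-,*01:01,-,-,-,*03:01,*06:04,*02:01,*04:01,*01:02,*03:01,*01:03,-
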