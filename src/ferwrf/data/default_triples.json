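{
"distratio_triples": [
[
55,
42,
50
],
[
24,
23,
57
],
[
57,
41,
55
],
[
40,
36,
25
],
[
36,
14,
63
],
[
61,
21,
16
],
[
42,
50,
44
],
[
66,
44,
23
],
[
26,
36,
58
],
[
66,
45,
15
],
[
46,
24,
49
],
[
65,
18,
12
],
[
24,
60,
3
],
[
56,
64,
62
],
[
19,
59,
58
],
[
41,
17,
53
],
[
66,
26,
24
],
[
48,
23,
19
],
[
61,
47,
37
],
[
56,
41,
16
],
[
50,
67,
38
],
[
12,
43,
58
],
[
55,
21,
1
],
[
40,
6,
39
],
[
19,
52,
20
],
[
26,
16,
64
],
[
46,
49,
56
],
[
52,
62,
65
],
[
56,
40,
39
],
[
60,
46,
42
],
[
38,
45,
24
],
[
48,
11,
49
],
[
63,
47,
22
],
[
50,
17,
23
],
[
61,
37,
66
],
[
59,
41,
54
],
[
62,
60,
63
],
[
20,
19,
52
],
[
63,
50,
25
],
[
57,
7,
52
],
[
3,
51,
1
],
[
7,
53,
44
],
[
21,
38,
58
],
[
14,
48,
25
],
[
10,
7,
45
],
[
57,
67,
64
],
[
42,
12,
54
],
[
12,
62,
6
],
[
47,
65,
37
],
[
8,
53,
15
],
[
64,
23,
62
],
[
55,
42,
54
],
[
16,
22,
19
],
[
50,
40,
47
],
[
63,
50,
38
],
[
64,
20,
19
],
[
45,
47,
62
],
[
67,
44,
22
],
[
58,
57,
10
],
[
64,
22,
62
],
[
36,
23,
37
],
[
44,
17,
39
],
[
26,
7,
5
],
[
49,
13,
63
],
[
53,
43,
24
],
[
49,
59,
57
],
[
23,
20,
41
],
[
43,
48,
52
],
[
64,
36,
49
],
[
22,
24,
42
],
[
2,
45,
36
],
[
13,
21,
65
],
[
26,
0,
61
],
[
64,
50,
13
],
[
41,
37,
45
],
[
54,
59,
48
],
[
26,
20,
18
],
[
16,
55,
57
],
[
54,
47,
66
],
[
22,
1,
58
],
[
67,
41,
46
],
[
58,
39,
21
],
[
39,
19,
64
],
[
66,
23,
43
]
],
"anglerelat_triples": [
[
22,
67,
61
],
[
64,
22,
46
],
[
36,
61,
66
],
[
21,
19,
24
],
[
59,
24,
43
],
[
67,
38,
40
],
[
43,
46,
26
],
[
17,
36,
43
],
[
59,
50,
64
],
[
44,
39,
57
],
[
13,
20,
17
],
[
9,
21,
47
],
[
24,
55,
23
],
[
48,
45,
55
],
[
36,
55,
3
],
[
54,
25,
39
],
[
47,
62,
25
],
[
45,
55,
38
],
[
17,
3,
67
],
[
60,
25,
20
],
[
36,
16,
48
],
[
48,
58,
56
],
[
39,
57,
38
],
[
45,
66,
8
],
[
25,
66,
40
],
[
62,
23,
0
],
[
48,
46,
25
],
[
18,
6,
57
],
[
38,
57,
63
],
[
21,
51,
56
],
[
63,
60,
24
],
[
22,
12,
62
],
[
39,
26,
8
],
[
7,
19,
59
],
[
57,
50,
2
],
[
26,
47,
67
],
[
7,
3,
63
],
[
46,
55,
36
],
[
36,
51,
41
],
[
57,
51,
42
],
[
26,
54,
22
],
[
40,
19,
42
],
[
7,
26,
19
],
[
2,
53,
56
],
[
59,
57,
45
],
[
40,
48,
52
],
[
54,
57,
58
],
[
2,
20,
55
],
[
41,
65,
26
],
[
7,
42,
66
],
[
46,
55,
10
],
[
17,
22,
36
],
[
44,
51,
56
],
[
17,
1,
42
],
[
49,
36,
47
],
[
43,
25,
20
],
[
59,
66,
39
],
[
7,
63,
46
],
[
22,
45,
20
],
[
57,
48,
64
],
[
18,
51,
12
],
[
51,
36,
38
],
[
38,
55,
4
],
[
18,
60,
11
],
[
41,
40,
18
],
[
47,
5,
39
],
[
52,
54,
59
],
[
3,
39,
54
],
[
45,
24,
42
],
[
47,
61,
43
],
[
64,
53,
67
],
[
17,
21,
64
],
[
66,
43,
58
],
[
58,
26,
62
],
[
56,
40,
8
],
[
48,
40,
42
],
[
13,
18,
25
],
[
48,
59,
40
],
[
51,
67,
39
],
[
61,
25,
51
],
[
5,
52,
38
],
[
38,
52,
54
],
[
61,
26,
57
],
[
47,
26,
24
],
[
6,
41,
65
],
[
59,
64,
47
],
[
44,
4,
47
],
[
19,
41,
5
]
]
}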