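# letter-bigram frequencies per million, derived from the
# packaged top-1000 word list under Zipfian rank weights
# columns: first_letter, second_letter, per_million
a	a	0.00
a	b	1868.12
a	c	3699.69
a	d	4616.80
a	e	0.00
a	f	764.60
a	g	1487.58
a	h	0.00
a	i	3237.27
a	j	0.00
a	k	1375.18
a	l	8468.66
a	m	2586.27
a	n	28387.01
a	o	0.00
a	p	892.77
a	q	0.00
a	r	9355.96
a	s	13245.27
a	t	17058.66
a	u	841.92
a	v	2652.20
a	w	647.18
a	x	97.79
a	y	3468.98
a	z	0.00
b	a	1497.13
b	b	0.00
b	c	0.00
b	d	0.00
b	e	8705.39
b	f	0.00
b	g	0.00
b	h	0.00
b	i	316.68
b	j	85.25
b	k	0.00
b	l	1640.91
b	m	0.00
b	n	0.00
b	o	2375.45
b	p	0.00
b	q	0.00
b	r	612.65
b	s	0.00
b	t	166.52
b	u	2634.07
b	v	0.00
b	w	0.00
b	x	0.00
b	y	2780.52
b	z	0.00
c	a	4318.89
c	b	0.00
c	c	156.94
c	d	0.00
c	e	4902.31
c	f	0.00
c	g	0.00
c	h	5744.40
c	i	934.15
c	j	0.00
c	k	1313.37
c	l	977.71
c	m	0.00
c	n	0.00
c	o	5053.24
c	p	0.00
c	q	0.00
c	r	484.45
c	s	0.00
c	t	1760.58
c	u	531.18
c	v	0.00
c	w	0.00
c	x	0.00
c	y	108.66
c	z	0.00
d	a	953.45
d	b	0.00
d	c	0.00
d	d	342.21
d	e	5241.56
d	f	52.25
d	g	136.63
d	h	0.00
d	i	2313.19
d	j	0.00
d	k	0.00
d	l	65.94
d	m	52.30
d	n	243.33
d	o	2586.11
d	p	0.00
d	q	0.00
d	r	531.45
d	s	542.93
d	t	0.00
d	u	780.01
d	v	0.00
d	w	0.00
d	x	0.00
d	y	537.82
d	z	0.00
e	a	7276.44
e	b	66.88
e	c	2644.69
e	d	5116.82
e	e	5257.59
e	f	1271.71
e	g	734.12
e	h	149.80
e	i	2192.91
e	j	0.00
e	k	239.49
e	l	3350.75
e	m	2842.40
e	n	11320.19
e	o	586.02
e	p	905.42
e	q	86.38
e	r	20695.13
e	s	5996.00
e	t	3806.65
e	u	0.00
e	v	3134.13
e	w	1620.47
e	x	730.25
e	y	2323.74
e	z	0.00
f	a	1549.45
f	b	0.00
f	c	0.00
f	d	0.00
f	e	2155.47
f	f	1143.93
f	g	0.00
f	h	0.00
f	i	2216.04
f	j	0.00
f	k	0.00
f	l	238.39
f	m	0.00
f	n	0.00
f	o	7046.20
f	p	0.00
f	q	0.00
f	r	2695.67
f	s	0.00
f	t	1204.84
f	u	411.10
f	v	0.00
f	w	0.00
f	x	0.00
f	y	0.00
f	z	0.00
g	a	1346.57
g	b	0.00
g	c	0.00
g	d	0.00
g	e	2679.87
g	f	0.00
g	g	62.90
g	h	3532.20
g	i	1086.12
g	j	0.00
g	k	0.00
g	l	288.47
g	m	0.00
g	n	244.65
g	o	2126.21
g	p	0.00
g	q	0.00
g	r	1408.37
g	s	208.99
g	t	84.97
g	u	350.36
g	v	0.00
g	w	0.00
g	x	0.00
g	y	0.00
g	z	0.00
h	a	16476.92
h	b	52.83
h	c	0.00
h	d	52.14
h	e	73221.61
h	f	0.00
h	g	0.00
h	h	0.00
h	i	12741.96
h	j	0.00
h	k	0.00
h	l	0.00
h	m	0.00
h	n	69.20
h	o	6903.60
h	p	0.00
h	q	0.00
h	r	1028.58
h	s	114.67
h	t	1841.46
h	u	721.45
h	v	0.00
h	w	0.00
h	x	0.00
h	y	245.64
h	z	0.00
i	a	725.53
i	b	280.91
i	c	4475.86
i	d	3676.52
i	e	1229.92
i	f	2127.41
i	g	2463.89
i	h	0.00
i	i	0.00
i	j	0.00
i	k	664.49
i	l	3949.97
i	m	3193.80
i	n	20240.54
i	o	2779.32
i	p	126.31
i	q	0.00
i	r	3404.99
i	s	13573.18
i	t	13599.78
i	u	0.00
i	v	1432.99
i	w	0.00
i	x	138.58
i	y	0.00
i	z	86.96
j	a	0.00
j	b	0.00
j	c	0.00
j	d	0.00
j	e	85.25
j	f	0.00
j	g	0.00
j	h	0.00
j	i	0.00
j	j	0.00
j	k	0.00
j	l	0.00
j	m	0.00
j	n	0.00
j	o	116.18
j	p	0.00
j	q	0.00
j	r	0.00
j	s	0.00
j	t	0.00
j	u	632.16
j	v	0.00
j	w	0.00
j	x	0.00
j	y	0.00
j	z	0.00
k	a	0.00
k	b	0.00
k	c	0.00
k	d	0.00
k	e	2667.21
k	f	0.00
k	g	0.00
k	h	0.00
k	i	685.18
k	j	0.00
k	k	0.00
k	l	0.00
k	m	0.00
k	n	898.36
k	o	0.00
k	p	0.00
k	q	0.00
k	r	0.00
k	s	80.98
k	t	0.00
k	u	0.00
k	v	0.00
k	w	0.00
k	x	0.00
k	y	63.83
k	z	0.00
l	a	3905.23
l	b	0.00
l	c	0.00
l	d	4657.67
l	e	6397.75
l	f	635.20
l	g	0.00
l	h	0.00
l	i	3986.57
l	j	0.00
l	k	255.32
l	l	5847.68
l	m	264.44
l	n	0.00
l	o	3135.13
l	p	178.11
l	q	0.00
l	r	156.59
l	s	959.18
l	t	742.49
l	u	451.07
l	v	279.60
l	w	278.66
l	x	0.00
l	y	2704.03
l	z	0.00
m	a	5210.57
m	b	797.10
m	c	0.00
m	d	0.00
m	e	8224.58
m	f	0.00
m	g	0.00
m	h	0.00
m	i	1829.32
m	j	0.00
m	k	0.00
m	l	0.00
m	m	370.40
m	n	0.00
m	o	3823.92
m	p	1153.90
m	q	0.00
m	r	796.62
m	s	742.81
m	t	0.00
m	u	1236.18
m	v	0.00
m	w	0.00
m	x	0.00
m	y	873.21
m	z	0.00
n	a	1598.64
n	b	0.00
n	c	1979.91
n	d	22080.95
n	e	7009.92
n	f	239.38
n	g	6735.34
n	h	0.00
n	i	1654.29
n	j	0.00
n	k	341.46
n	l	1002.19
n	m	255.32
n	n	371.48
n	o	5980.93
n	p	0.00
n	q	0.00
n	r	0.00
n	s	1315.11
n	t	6997.72
n	u	533.73
n	v	66.96
n	w	0.00
n	x	0.00
n	y	1699.46
n	z	0.00
o	a	615.59
o	b	527.94
o	c	1036.98
o	d	1663.52
o	e	413.08
o	f	26726.21
o	g	350.92
o	h	102.23
o	i	766.36
o	j	0.00
o	k	801.43
o	l	2362.20
o	m	5519.34
o	n	13197.45
o	o	3338.90
o	p	1700.41
o	q	0.00
o	r	13100.69
o	s	2675.83
o	t	5662.20
o	u	13731.56
o	v	1731.52
o	w	4827.70
o	x	63.28
o	y	133.93
o	z	0.00
p	a	1922.25
p	b	0.00
p	c	0.00
p	d	0.00
p	e	3233.45
p	f	0.00
p	g	0.00
p	h	67.66
p	i	510.45
p	j	0.00
p	k	0.00
p	l	2264.50
p	m	193.40
p	n	0.00
p	o	2259.94
p	p	667.09
p	q	0.00
p	r	1923.18
p	s	175.10
p	t	156.02
p	u	889.05
p	v	0.00
p	w	0.00
p	x	0.00
p	y	75.89
p	z	0.00
q	a	0.00
q	b	0.00
q	c	0.00
q	d	0.00
q	e	0.00
q	f	0.00
q	g	0.00
q	h	0.00
q	i	0.00
q	j	0.00
q	k	0.00
q	l	0.00
q	m	0.00
q	n	0.00
q	o	0.00
q	p	0.00
q	q	0.00
q	r	0.00
q	s	0.00
q	t	0.00
q	u	527.94
q	v	0.00
q	w	0.00
q	x	0.00
q	y	0.00
q	z	0.00
r	a	2651.52
r	b	0.00
r	c	412.64
r	d	1410.97
r	e	15494.88
r	f	195.03
r	g	352.09
r	h	175.10
r	i	3355.99
r	j	0.00
r	k	854.80
r	l	1176.98
r	m	1153.58
r	n	1456.83
r	o	6086.88
r	p	102.43
r	q	0.00
r	r	342.71
r	s	3171.63
r	t	2771.90
r	u	508.91
r	v	257.83
r	w	0.00
r	x	0.00
r	y	2024.40
r	z	0.00
s	a	2341.59
s	b	74.15
s	c	578.60
s	d	0.00
s	e	8155.79
s	f	0.00
s	g	0.00
s	h	3206.63
s	i	3398.70
s	j	0.00
s	k	471.91
s	l	279.84
s	m	424.70
s	n	61.41
s	o	4172.92
s	p	903.44
s	q	77.59
s	r	0.00
s	s	2005.91
s	t	9627.80
s	u	1869.07
s	v	0.00
s	w	154.08
s	x	0.00
s	y	364.35
s	z	0.00
t	a	3649.33
t	b	0.00
t	c	169.12
t	d	0.00
t	e	6931.24
t	f	0.00
t	g	0.00
t	h	82511.33
t	i	4562.36
t	j	0.00
t	k	0.00
t	l	747.36
t	m	189.95
t	n	0.00
t	o	16905.67
t	p	0.00
t	q	0.00
t	r	1968.83
t	s	1707.36
t	t	1701.08
t	u	1474.29
t	v	0.00
t	w	1169.14
t	x	0.00
t	y	1120.29
t	z	0.00
u	a	831.21
u	b	588.10
u	c	1724.99
u	d	509.62
u	e	553.08
u	f	0.00
u	g	1854.00
u	h	0.00
u	i	426.88
u	j	0.00
u	k	0.00
u	l	3499.18
u	m	668.41
u	n	3751.06
u	o	0.00
u	p	1772.13
u	q	0.00
u	r	4251.02
u	s	4567.97
u	t	5632.06
u	u	0.00
u	v	0.00
u	w	0.00
u	x	0.00
u	y	0.00
u	z	0.00
v	a	535.13
v	b	0.00
v	c	0.00
v	d	0.00
v	e	8825.48
v	f	0.00
v	g	0.00
v	h	0.00
v	i	968.86
v	j	0.00
v	k	0.00
v	l	0.00
v	m	0.00
v	n	0.00
v	o	203.36
v	p	0.00
v	q	0.00
v	r	0.00
v	s	0.00
v	t	0.00
v	u	0.00
v	v	0.00
v	w	0.00
v	x	0.00
v	y	65.44
v	z	0.00
w	a	8340.65
w	b	0.00
w	c	0.00
w	d	0.00
w	e	5264.87
w	f	0.00
w	g	0.00
w	h	6893.58
w	i	6264.30
w	j	0.00
w	k	0.00
w	l	153.98
w	m	0.00
w	n	1379.74
w	o	3472.28
w	p	0.00
w	q	0.00
w	r	286.94
w	s	161.36
w	t	78.41
w	u	0.00
w	v	0.00
w	w	0.00
w	x	0.00
w	y	0.00
w	z	0.00
x	a	169.93
x	b	0.00
x	c	88.00
x	d	0.00
x	e	0.00
x	f	0.00
x	g	0.00
x	h	0.00
x	i	0.00
x	j	0.00
x	k	0.00
x	l	0.00
x	m	0.00
x	n	0.00
x	o	0.00
x	p	238.85
x	q	0.00
x	r	0.00
x	s	0.00
x	t	233.47
x	u	0.00
x	v	0.00
x	w	0.00
x	x	0.00
x	y	0.00
x	z	0.00
y	a	0.00
y	b	148.09
y	c	0.00
y	d	0.00
y	e	1749.50
y	f	0.00
y	g	0.00
y	h	0.00
y	i	111.22
y	j	0.00
y	k	0.00
y	l	0.00
y	m	0.00
y	n	0.00
y	o	2592.54
y	p	116.47
y	q	0.00
y	r	0.00
y	s	532.72
y	t	273.38
y	u	0.00
y	v	0.00
y	w	0.00
y	x	0.00
y	y	0.00
y	z	0.00
z	a	0.00
z	b	0.00
z	c	0.00
z	d	0.00
z	e	86.96
z	f	0.00
z	g	0.00
z	h	0.00
z	i	0.00
z	j	0.00
z	k	0.00
z	l	0.00
z	m	0.00
z	n	0.00
z	o	0.00
z	p	0.00
z	q	0.00
z	r	0.00
z	s	0.00
z	t	0.00
z	u	0.00
z	v	0.00
z	w	0.00
z	x	0.00
z	y	0.00
z	z	0.00
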