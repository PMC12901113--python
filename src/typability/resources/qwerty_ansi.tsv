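# US ANSI QWERTY layout for touch typing.
# Columns: key_id, base_char, shifted_char, row, column, hand, finger, side
# Rows: 0 = number row, 1 = top letter row, 2 = home row, 3 = bottom letter row,
# 4 = space row.  Fingers: 1 left pinky .. 4 left index, 5/6 thumbs,
# 7 right index .. 10 right pinky.  base_char "<space>" encodes the space bar.
# "-" in shifted_char means the key produces nothing extra with shift that we
# support (the loader simply skips it).
grave	`	~	0	0.0	left	1	left
d1	1	!	0	1.0	left	1	left
d2	2	@	0	2.0	left	2	left
d3	3	#	0	3.0	left	3	left
d4	4	$	0	4.0	left	4	left
d5	5	%	0	5.0	left	4	left
d6	6	^	0	6.0	right	7	right
d7	7	&	0	7.0	right	7	right
d8	8	*	0	8.0	right	8	right
d9	9	(	0	9.0	right	9	right
d0	0	)	0	10.0	right	10	right
minus	-	_	0	11.0	right	10	right
equal	=	+	0	12.0	right	10	right
q	q	Q	1	1.5	left	1	left
w	w	W	1	2.5	left	2	left
e	e	E	1	3.5	left	3	left
r	r	R	1	4.5	left	4	left
t	t	T	1	5.5	left	4	left
y	y	Y	1	6.5	right	7	right
u	u	U	1	7.5	right	7	right
i	i	I	1	8.5	right	8	right
o	o	O	1	9.5	right	9	right
p	p	P	1	10.5	right	10	right
lbracket	[	{	1	11.5	right	10	right
rbracket	]	}	1	12.5	right	10	right
backslash	\	|	1	13.5	right	10	right
a	a	A	2	1.75	left	1	left
s	s	S	2	2.75	left	2	left
d	d	D	2	3.75	left	3	left
f	f	F	2	4.75	left	4	left
g	g	G	2	5.75	left	4	left
h	h	H	2	6.75	right	7	right
j	j	J	2	7.75	right	7	right
k	k	K	2	8.75	right	8	right
l	l	L	2	9.75	right	9	right
semicolon	;	:	2	10.75	right	10	right
quote	'	"	2	11.75	right	10	right
z	z	Z	3	2.25	left	1	left
x	x	X	3	3.25	left	2	left
c	c	C	3	4.25	left	3	left
v	v	V	3	5.25	left	4	left
b	b	B	3	6.25	left	4	left
n	n	N	3	7.25	right	7	right
m	m	M	3	8.25	right	7	right
comma	,	<	3	9.25	right	8	right
period	.	>	3	10.25	right	9	right
slash	/	?	3	11.25	right	10	right
space	<space>	-	4	5.0	thumb	6	neutral
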