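organism	group	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19	20	21	22	23	24
V. vinifera	vascular plant	-	3	4	-	3	3	2	-	-	2	2	1	-	-	-	-	-	2	-	-	-	1	-	-
A. thaliana	vascular plant	-	3	3	-	1	1	1	-	-	2	1	1	-	-	-	-	-	2	-	-	-	1	-	-
Z. mays	vascular plant	-	6	5	-	2	1	1	-	-	3	1	1	-	-	-	-	-	3	-	-	-	1	-	-
O. sativa	vascular plant	-	5	5	-	1	1	1	-	-	2	1	2	-	-	-	-	-	2	-	-	-	1	-	-
P. patens	moss	-	2	5	-	2	1	1	-	-	1	5	1	-	-	-	-	-	-	-	-	1	-	1	-
C. reinhardtii	alga	-	1	-	-	2	1	-	-	-	1	1	1	-	-	-	-	-	-	-	-	-	-	-	1
O. tauri	alga	-	-	1	-	1	-	-	-	-	1	1	1	-	-	-	-	-	-	-	-	-	1	-	-
H. sapiens	mammal	6	1	4	1	1	1	1	1	1	-	-	-	-	-	-	1	-	1	-	-	-	-	-	-
M. musculus	mammal	7	1	4	1	1	1	1	1	1	-	-	-	-	-	-	1	-	1	-	-	-	-	-	-
R. norvegicus	mammal	7	1	4	-	1	1	1	1	1	-	-	-	-	-	-	1	-	1	-	-	-	-	-	-
Fungi	fungus	+	-	-	+	+	-	-	-	-	+	-	-	-	+	+	+	-	+	-	-	-	-	-	-
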