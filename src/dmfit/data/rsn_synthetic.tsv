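# Synthetic resting-state network masks for the 90-region synthetic parcellation.
# Not anatomical: index sets fabricated for testing mask-overlap scoring.
# columns: network region_index(0-based)
VN	0
VN	1
VN	2
VN	3
VN	4
VN	5
VN	6
VN	7
VN	8
VN	9
VN	10
VN	11
SN	12
SN	13
SN	14
SN	15
SN	16
SN	17
SN	18
SN	19
SN	20
SN	21
SN	22
SN	23
MN	24
MN	25
MN	26
MN	27
MN	28
MN	29
MN	30
MN	31
MN	32
MN	33
MN	34
MN	35
EXEC	36
EXEC	37
EXEC	38
EXEC	39
EXEC	40
EXEC	41
EXEC	42
EXEC	43
EXEC	44
EXEC	45
EXEC	46
EXEC	47
EXEC	48
EXEC	49
EXEC	63
DMN	50
DMN	51
DMN	52
DMN	53
DMN	54
DMN	55
DMN	56
DMN	57
DMN	58
DMN	59
DMN	60
DMN	61
DMN	62
DMN	63
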