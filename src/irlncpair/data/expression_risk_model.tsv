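ID	coef	HR	HR.95L	HR.95H	p_value
AP001469.3	0.574505872	1.776252615	0.998051245	3.161233822	0.050780302
AP001453.2	-0.363495071	0.695242154	0.432289518	1.118143358	0.133783345
AC007128.1	0.427241742	1.533023213	0.924508885	2.542063371	0.097768947
AC124067.4	-0.269272158	0.763935316	0.611645819	0.954142331	0.017606639
LINC00513	-0.419186774	0.657581365	0.470812319	0.918440818	0.013930483
FENDRR	-0.310222378	0.733283872	0.517954308	1.038132571	0.080294969
AL137782.1	-0.74476217	0.474847219	0.231960611	0.972061078	0.041601358
NKILA	0.514359624	1.672567087	1.217886075	2.296997001	0.001484107
AL590483.1	-0.773741406	0.461283985	0.268857903	0.79143262	0.004966124
AC010973.2	1.34334251	3.831830054	2.112475134	6.950577227	9.80E-06
AL354993.2	0.422350358	1.525542918	0.972653578	2.392713343	0.065882942
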