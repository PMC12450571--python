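mature_id	sim_microRNAome_s001
syn-miR-0001-3p	7.432484334
syn-miR-0002-5p	2861.55975
syn-miR-0003-3p	5.738977924
syn-miR-0004-3p	10018.36014
syn-miR-0005-5p	14.47533824
syn-miR-0006-5p	2219.727631
syn-miR-0006-3p	1704.655957
syn-miR-0007-5p	4445.871539
syn-miR-0007-3p	2868.313406
syn-miR-0008-5p	16081.33039
syn-miR-0008-3p	2078.947088
syn-miR-0009-5p	15121.846
syn-miR-0009-3p	6083.163762
syn-miR-0010-5p	2865.56089
syn-miR-0010-3p	23223.41456
syn-miR-0011-5p	22.30862788
syn-miR-0011-3p	2.01150063
syn-miR-0012-5p	49.54211345
syn-miR-0013-3p	137.5724702
syn-miR-0014-3p	8.815652435
syn-miR-0015-5p	6.182942547
syn-miR-0015-3p	36.34925398
syn-miR-0016-5p	41.62343592
syn-miR-0016-3p	146.6632141
syn-miR-0017-5p	7.765812885
syn-miR-0017-3p	83.13284792
syn-miR-0018-5p	16.90165839
syn-miR-0018-3p	38.30287966
syn-miR-0019-5p	1949.168484
syn-miR-0020-3p	2356.106349
syn-miR-0021-5p	54.47612889
syn-miR-0021-3p	12.33355714
syn-miR-0022-3p	2162.052178
syn-miR-0023-5p	3187.694406
syn-miR-0023-3p	3179.967922
syn-miR-0024-5p	1912.966364
syn-miR-0025-5p	174.672951
syn-miR-0025-3p	391.3392604
syn-miR-0026-3p	1992.869507
syn-miR-0027-5p	8879.852201
syn-miR-0028-5p	2086.094666
syn-miR-0028-3p	3850.161209
syn-miR-0029-5p	29.26299727
syn-miR-0029-3p	56.93607832
syn-miR-0030-5p	7023.795426
syn-miR-0030-3p	3488.681756
syn-miR-0031-5p	8345.764052
syn-miR-0031-3p	4880.29281
syn-miR-0032-5p	644.5906852
syn-miR-0032-3p	22820.57475
syn-miR-0033-5p	98.54195405
syn-miR-0033-3p	47.50315612
syn-miR-0034-5p	179.6935216
syn-miR-0035-5p	131.9335484
syn-miR-0036-5p	20.77229154
syn-miR-0036-3p	53.61299596
syn-miR-0037-3p	108.7343359
syn-miR-0038-5p	34.51796761
syn-miR-0038-3p	15.86438324
syn-miR-0039-5p	3.086442104
syn-miR-0039-3p	21.25096788
syn-miR-0040-5p	2032.40673
syn-miR-0040-3p	2427.317187
syn-miR-0041-5p	11393.48597
syn-miR-0042-5p	26.27317889
syn-miR-0042-3p	89.07038368
syn-miR-0043-5p	5538.552297
syn-miR-0044-5p	7675.692345
syn-miR-0045-3p	16160.50543
syn-miR-0046-5p	4.341015171
syn-miR-0046-3p	16.55277777
syn-miR-0047-5p	2587.076326
syn-miR-0048-5p	71.34398057
syn-miR-0048-3p	9.809852684
syn-miR-0049-5p	4089.711944
syn-miR-0050-5p	1501.797475
syn-miR-0051-5p	1749.979981
syn-miR-0051-3p	6789.440142
syn-miR-0052-5p	4977.751069
syn-miR-0052-3p	4729.196779
syn-miR-0053-5p	6361.575803
syn-miR-0053-3p	3781.781489
syn-miR-0054-5p	5442.834997
syn-miR-0055-3p	1925.418931
syn-miR-0056-5p	2.172411305
syn-miR-0056-3p	20.65758586
syn-miR-0057-5p	21057.72263
syn-miR-0058-5p	21.41080194
syn-miR-0058-3p	11.52179991
syn-miR-0059-5p	137.7319785
syn-miR-0060-5p	19.01813236
syn-miR-0060-3p	112.8684321
syn-miR-0061-5p	689.0012419
syn-miR-0061-3p	1286.313565
syn-miR-0062-5p	2231.367713
syn-miR-0062-3p	1889.969793
syn-miR-0063-5p	10.40926141
syn-miR-0064-5p	7418.854941
syn-miR-0064-3p	1583.829716
syn-miR-0065-5p	27.13350608
syn-miR-0066-5p	3874.919293
syn-miR-0066-3p	14386.47257
syn-miR-0067-5p	1164.224517
syn-miR-0068-5p	8676.539232
syn-miR-0068-3p	4802.053724
syn-miR-0069-5p	3905.120164
syn-miR-0070-5p	15937.90392
syn-miR-0070-3p	320.282931
syn-miR-0071-5p	4800.546077
syn-miR-0072-5p	5854.547615
syn-miR-0072-3p	21972.43772
syn-miR-0073-5p	12342.67918
syn-miR-0073-3p	3860.103138
syn-miR-0074-5p	56.10428379
syn-miR-0074-3p	21.63215165
syn-miR-0075-5p	19.09876827
syn-miR-0075-3p	81.45502621
syn-miR-0076-5p	9.804034504
syn-miR-0076-3p	63.82568076
syn-miR-0077-5p	4546.06818
syn-miR-0077-3p	2611.335597
syn-miR-0078-5p	13787.62664
syn-miR-0078-3p	2015.87374
syn-miR-0079-3p	25.95538832
syn-miR-0080-5p	11.03015533
syn-miR-0081-5p	23.06528704
syn-miR-0082-5p	9.881390974
syn-miR-0082-3p	30.3628052
syn-miR-0083-5p	15.19312866
syn-miR-0083-3p	223.3743012
syn-miR-0084-5p	65.21200461
syn-miR-0085-5p	3.695831735
syn-miR-0085-3p	24.67566023
syn-miR-0086-3p	4619.642117
syn-miR-0087-5p	710.330637
syn-miR-0087-3p	2014.785484
syn-miR-0088-5p	33.21761217
syn-miR-0088-3p	23.73304302
syn-miR-0089-5p	25.7044303
syn-miR-0090-3p	20.00265737
syn-miR-0091-5p	1467.736941
syn-miR-0091-3p	1717.745068
syn-miR-0092-5p	4107.790035
syn-miR-0092-3p	2821.615296
syn-miR-0093-5p	5892.385319
syn-miR-0094-3p	2940.795016
syn-miR-0095-5p	2814.120939
syn-miR-0095-3p	16003.24838
syn-miR-0096-5p	3050.951718
syn-miR-0097-5p	9411.701518
syn-miR-0098-3p	2019.593546
syn-miR-0099-5p	8.856635072
syn-miR-0099-3p	70.23037152
syn-miR-0100-3p	3078.635294
syn-miR-0101-5p	5898.151505
syn-miR-0101-3p	4399.701127
syn-miR-0102-5p	4765.31892
syn-miR-0102-3p	65817.43272
syn-miR-0103-5p	2268.599718
syn-miR-0103-3p	4572.266404
syn-miR-0104-5p	39.54231564
syn-miR-0104-3p	45.37043477
syn-miR-0105-5p	4279.079745
syn-miR-0106-5p	5.502818499
syn-miR-0107-5p	7978.886197
syn-miR-0107-3p	5615.668261
syn-miR-0108-5p	148.4316446
syn-miR-0108-3p	95.23031238
syn-miR-0109-5p	6280.551303
syn-miR-0109-3p	4652.950323
syn-miR-0110-5p	4280.28665
syn-miR-0110-3p	18904.48027
syn-miR-0111-5p	189.6962154
syn-miR-0111-3p	11.18071158
syn-miR-0112-3p	480.7702752
syn-miR-0113-5p	10.47685728
syn-miR-0114-5p	16.3465752
syn-miR-0114-3p	52.19299156
syn-miR-0115-5p	21.53307864
syn-miR-0115-3p	48.48209891
syn-miR-0116-5p	29.81994093
syn-miR-0116-3p	33.26834089
syn-miR-0117-5p	2265.641643
syn-miR-0117-3p	24941.41746
syn-miR-0118-5p	4414.272276
syn-miR-0118-3p	2412.138347
syn-miR-0119-5p	16.77340297
syn-miR-0120-3p	75.04486813
syn-miR-0121-3p	4301.286018
syn-miR-0122-5p	48.92994281
syn-miR-0122-3p	31.11036586
syn-miR-0123-5p	3049.854075
syn-miR-0123-3p	2239.2325
syn-miR-0124-5p	4208.821918
syn-miR-0124-3p	12254.6078
syn-miR-0125-3p	1084.681172
syn-miR-0126-5p	53.80625723
syn-miR-0126-3p	58.57179863
syn-miR-0127-5p	784.1750895
syn-miR-0127-3p	1978.27916
syn-miR-0128-5p	8096.957283
syn-miR-0128-3p	1298.494948
syn-miR-0129-5p	5703.750256
syn-miR-0130-5p	1232.519085
syn-miR-0130-3p	22000.97625
syn-miR-0131-5p	55.76024069
syn-miR-0131-3p	165.9413222
syn-miR-0132-3p	35.77813855
syn-miR-0133-5p	5394.264514
syn-miR-0133-3p	3569.853294
syn-miR-0134-5p	904.22846
syn-miR-0135-5p	734.1785536
syn-miR-0135-3p	6615.33292
syn-miR-0136-5p	7.760888497
syn-miR-0137-5p	1155.904005
syn-miR-0137-3p	1174.793613
syn-miR-0138-5p	8.964746782
syn-miR-0138-3p	100.4204024
syn-miR-0139-5p	1813.22486
syn-miR-0139-3p	2615.456001
syn-miR-0140-5p	512.0691525
syn-miR-0140-3p	5710.500566
syn-miR-0141-5p	2118.312858
syn-miR-0141-3p	5616.631699
syn-miR-0142-5p	7263.374694
syn-miR-0143-5p	15004.24656
syn-miR-0143-3p	6799.461206
syn-miR-0144-5p	55.78585793
syn-miR-0144-3p	8.482349303
syn-miR-0145-5p	238.1463767
syn-miR-0145-3p	61.77976266
syn-miR-0146-3p	3349.750065
syn-miR-0147-5p	2162.452524
syn-miR-0147-3p	9375.549545
syn-miR-0148-5p	1194.172232
syn-miR-0148-3p	6132.052064
syn-miR-0149-5p	175933.2412
syn-miR-0149-3p	5732.707431
syn-miR-0150-5p	2.700264254
syn-miR-0150-3p	193.6045679
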