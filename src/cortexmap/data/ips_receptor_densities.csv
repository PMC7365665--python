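area,receptor,mean,sd
AIP,AMPA,506.5,70.1
AIP,kainate,541.0,101.0
AIP,NMDA,1284.4,124.5
AIP,GABAA,1564.8,238.1
AIP,GABAB,1958.2,277.9
AIP,GABAA/BZ,1565.2,226.9
AIP,M1,924.0,154.5
AIP,M2,128.2,39.3
AIP,M3,819.3,91.8
AIP,alpha1,409.3,46.0
AIP,alpha2,306.0,53.3
AIP,5-HT1A,348.6,35.2
AIP,5-HT2,319.4,75.9
AIP,A1,800.7,180.4
AIP,D1,77.3,5.1
LIPd,AMPA,485.5,67.4
LIPd,kainate,592.5,60.7
LIPd,NMDA,1397.0,199.1
LIPd,GABAA,1621.0,159.6
LIPd,GABAB,2012.4,290.6
LIPd,GABAA/BZ,2097.2,350.5
LIPd,M1,1028.2,186.6
LIPd,M2,136.7,41.2
LIPd,M3,788.6,113.8
LIPd,alpha1,374.2,28.3
LIPd,alpha2,291.7,25.6
LIPd,5-HT1A,323.3,50.1
LIPd,5-HT2,364.9,73.2
LIPd,A1,832.3,183.2
LIPd,D1,82.0,7.3
LIPv,AMPA,443.2,64.8
LIPv,kainate,551.0,34.3
LIPv,NMDA,1241.1,189.3
LIPv,GABAA,1508.9,160.3
LIPv,GABAB,1783.3,250.3
LIPv,GABAA/BZ,1832.0,167.5
LIPv,M1,912.2,135.7
LIPv,M2,143.3,38.0
LIPv,M3,722.4,100.9
LIPv,alpha1,310.6,25.5
LIPv,alpha2,271.9,23.7
LIPv,5-HT1A,209.0,22.2
LIPv,5-HT2,361.8,62.8
LIPv,A1,834.4,127.6
LIPv,D1,77.6,6.4
PEipe,AMPA,522.3,53.4
PEipe,kainate,526.7,96.6
PEipe,NMDA,1203.0,236.5
PEipe,GABAA,1570.2,226.5
PEipe,GABAB,2064.6,269.9
PEipe,GABAA/BZ,1792.6,164.1
PEipe,M1,943.6,111.0
PEipe,M2,134.2,49.6
PEipe,M3,766.0,80.1
PEipe,alpha1,390.0,36.8
PEipe,alpha2,278.6,53.0
PEipe,5-HT1A,355.6,55.9
PEipe,5-HT2,323.5,76.8
PEipe,A1,733.6,152.8
PEipe,D1,81.6,8.8
PEipi,AMPA,483.4,85.4
PEipi,kainate,495.8,95.7
PEipi,NMDA,1190.1,135.4
PEipi,GABAA,1549.1,194.4
PEipi,GABAB,2024.8,286.9
PEipi,GABAA/BZ,1802.3,114.8
PEipi,M1,933.4,77.5
PEipi,M2,114.6,40.6
PEipi,M3,800.2,108.3
PEipi,alpha1,389.2,39.4
PEipi,alpha2,288.0,53.5
PEipi,5-HT1A,312.3,50.5
PEipi,5-HT2,311.2,55.8
PEipi,A1,789.8,111.2
PEipi,D1,79.2,7.1
MIPv,AMPA,435.0,72.9
MIPv,kainate,517.2,62.9
MIPv,NMDA,1173.8,217.1
MIPv,GABAA,1549.0,175.1
MIPv,GABAB,1875.7,263.9
MIPv,GABAA/BZ,1927.6,162.7
MIPv,M1,903.8,93.7
MIPv,M2,132.0,34.9
MIPv,M3,723.2,97.2
MIPv,alpha1,342.9,33.7
MIPv,alpha2,288.0,44.9
MIPv,5-HT1A,245.8,62.6
MIPv,5-HT2,356.0,51.8
MIPv,A1,826.9,131.0
MIPv,D1,79.1,6.7
MIPd,AMPA,475.7,70.9
MIPd,kainate,562.3,84.8
MIPd,NMDA,1210.8,186.9
MIPd,GABAA,1598.3,171.9
MIPd,GABAB,2020.1,321.2
MIPd,GABAA/BZ,1779.9,93.0
MIPd,M1,951.8,102.7
MIPd,M2,126.4,36.5
MIPd,M3,760.7,81.7
MIPd,alpha1,406.0,39.1
MIPd,alpha2,291.5,47.7
MIPd,5-HT1A,307.0,82.2
MIPd,5-HT2,350.0,66.4
MIPd,A1,796.5,154.9
MIPd,D1,85.8,6.7
VIPl,AMPA,431.8,75.4
VIPl,kainate,423.2,91.4
VIPl,NMDA,1130.1,151.7
VIPl,GABAA,1445.1,243.6
VIPl,GABAB,1829.8,203.3
VIPl,GABAA/BZ,1606.6,142.8
VIPl,M1,858.7,81.0
VIPl,M2,121.6,41.3
VIPl,M3,753.2,76.7
VIPl,alpha1,368.3,27.3
VIPl,alpha2,272.5,49.9
VIPl,5-HT1A,264.3,28.7
VIPl,5-HT2,317.7,69.8
VIPl,A1,718.4,120.8
VIPl,D1,84.3,9.5
VIPm,AMPA,426.7,69.3
VIPm,kainate,453.9,90.1
VIPm,NMDA,1104.5,212.8
VIPm,GABAA,1534.2,180.7
VIPm,GABAB,1847.5,346.4
VIPm,GABAA/BZ,1714.7,78.8
VIPm,M1,856.7,83.7
VIPm,M2,119.9,41.3
VIPm,M3,725.3,99.9
VIPm,alpha1,338.2,49.7
VIPm,alpha2,270.2,48.5
VIPm,5-HT1A,244.6,34.3
VIPm,5-HT2,321.1,59.0
VIPm,A1,806.6,148.1
VIPm,D1,76.3,9.1
PIP,AMPA,348.6,58.7
PIP,kainate,494.9,61.3
PIP,NMDA,1241.2,119.2
PIP,GABAA,1400.7,162.5
PIP,GABAB,1702.0,303.9
PIP,GABAA/BZ,1629.8,125.5
PIP,M1,857.7,134.0
PIP,M2,142.5,42.3
PIP,M3,666.3,104.3
PIP,alpha1,292.3,64.7
PIP,alpha2,310.5,27.0
PIP,5-HT1A,110.6,54.6
PIP,5-HT2,336.4,74.8
PIP,A1,795.1,136.8
PIP,D1,73.3,8.3
LOP,AMPA,361.6,59.0
LOP,kainate,573.1,69.3
LOP,NMDA,1190.1,146.2
LOP,GABAA,1396.3,157.7
LOP,GABAB,1614.2,224.2
LOP,GABAA/BZ,1774.2,175.3
LOP,M1,885.3,65.5
LOP,M2,140.4,33.3
LOP,M3,707.3,100.3
LOP,alpha1,317.0,47.6
LOP,alpha2,296.3,25.1
LOP,5-HT1A,143.2,57.1
LOP,5-HT2,336.1,67.3
LOP,A1,758.4,135.1
LOP,D1,75.5,6.0
V3A,AMPA,378.0,78.5
V3A,kainate,492.2,69.4
V3A,NMDA,1189.0,120.1
V3A,GABAA,1455.3,294.1
V3A,GABAB,1652.9,280.1
V3A,GABAA/BZ,1647.1,51.5
V3A,M1,878.7,125.0
V3A,M2,133.2,25.4
V3A,M3,742.1,100.9
V3A,alpha1,293.6,62.0
V3A,alpha2,292.1,50.2
V3A,5-HT1A,144.9,50.3
V3A,5-HT2,332.7,71.0
V3A,A1,810.6,236.9
V3A,D1,74.1,11.9
V3d,AMPA,317.9,66.2
V3d,kainate,452.0,82.4
V3d,NMDA,1213.6,129.3
V3d,GABAA,1476.8,405.2
V3d,GABAB,1644.7,289.8
V3d,GABAA/BZ,1627.7,120.2
V3d,M1,906.6,99.0
V3d,M2,178.9,60.5
V3d,M3,727.6,93.5
V3d,alpha1,249.6,45.8
V3d,alpha2,294.6,37.8
V3d,5-HT1A,87.9,37.3
V3d,5-HT2,331.0,74.0
V3d,A1,827.0,192.6
V3d,D1,74.9,7.0
V6Ad,AMPA,427.2,71.1
V6Ad,kainate,536.3,87.4
V6Ad,NMDA,1148.7,116.5
V6Ad,GABAA,1450.0,265.0
V6Ad,GABAB,1679.1,335.4
V6Ad,GABAA/BZ,1698.1,141.4
V6Ad,M1,904.3,74.3
V6Ad,M2,118.3,36.7
V6Ad,M3,710.1,92.9
V6Ad,alpha1,329.1,35.5
V6Ad,alpha2,248.6,36.0
V6Ad,5-HT1A,245.9,46.3
V6Ad,5-HT2,323.2,68.8
V6Ad,A1,782.7,147.4
V6Ad,D1,80.4,8.1
V6Av,AMPA,373.8,71.3
V6Av,kainate,483.1,59.5
V6Av,NMDA,1115.6,71.1
V6Av,GABAA,1393.7,193.3
V6Av,GABAB,1595.7,277.0
V6Av,GABAA/BZ,1543.9,116.1
V6Av,M1,857.0,64.7
V6Av,M2,134.3,32.7
V6Av,M3,706.8,91.5
V6Av,alpha1,305.4,29.3
V6Av,alpha2,286.3,23.2
V6Av,5-HT1A,136.9,38.7
V6Av,5-HT2,336.9,52.5
V6Av,A1,790.1,106.2
V6Av,D1,76.0,4.6
V6,AMPA,319.2,57.7
V6,kainate,457.8,58.9
V6,NMDA,1073.0,142.3
V6,GABAA,1317.3,233.8
V6,GABAB,1505.0,397.6
V6,GABAA/BZ,1514.6,34.2
V6,M1,832.1,66.2
V6,M2,136.7,40.6
V6,M3,675.9,117.0
V6,alpha1,260.1,47.5
V6,alpha2,274.9,37.1
V6,5-HT1A,99.8,39.4
V6,5-HT2,301.8,73.5
V6,A1,754.1,129.2
V6,D1,71.5,6.7
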