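analyte,qc_level,accuracy_pct,intra_day_rsd,inter_day_rsd,recovery_mean,recovery_rsd,ee_mean,ee_rsd,me_mean,me_rsd,isnme_mean,isnme_rsd,identity_consistent
ATE,H,95.9,0.8,0.7,89.8,4.3,94.2,5.1,-4.5,6.3,-5.8,3.4,True
ATE,M,95.4,1,1.0,90.0,1.3,90.5,6.9,-0.1,7.7,-3.2,2.8,True
ATE,L,85.6,2.5,2.4,95.1,4.7,93.3,8.9,2.6,9.6,-1.2,5.0,True
CLN,H,94.6,3.4,2.8,84.8,1.3,89.7,4.7,-5.2,5.6,-7.5,6.5,True
CLN,M,91.9,3.5,3.2,85.8,6.0,89.0,7.0,-3.2,7.9,-5.2,9.8,True
CLN,L,58.8,14,13.1,108.3,18.2,80.2,10.2,36,20.6,40.8,13.2,True
HCTZ,H,96.4,2.7,3.6,106.4,2.4,86.6,10.9,23.8,8.6,22.1,9.2,True
HCTZ,M,108.2,0.9,1.3,135,1.7,92.9,13.4,46.8,11.4,48.5,10.9,True
HCTZ,L,86.9,25.6,30.3,142.3,2.2,84.8,8.2,69.1,9.7,69.3,9.6,True
DOX,H,98.4,2.2,3.2,133.9,1.2,98.8,0.4,35.6,1.6,29.6,0.6,True
DOX,M,109.5,4.3,6.8,149.6,1.8,103.3,1.3,44.9,3.2,41.9,3.2,True
DOX,L,89.7,3.2,9.4,159.5,14.0,118.9,11.0,33.9,3.0,27.9,3.8,True
OLM,H,97.6,2.6,3.6,97.2,2.1,97.4,4.3,-0.1,6.6,-5.5,16.0,True
OLM,M,93.5,2.3,3.4,108.9,6.8,97.0,7.1,12.7,12.7,8.0,6.8,True
OLM,L,81.9,3.1,4.7,112.3,8.8,95.4,9.3,18,13.3,18.4,10.0,True
CHL,H,96.7,4.3,5.0,73.9,7.4,93.7,12.8,-20.2,13.6,-34.7,6.8,True
CHL,M,97.1,3.8,5.0,79.6,2.5,95.0,6.6,-15.9,11.8,-19.5,13.9,True
CHL,L,92.7,5.9,8.4,84.1,15.5,98.0,8.6,-13.4,19.6,-22.3,16.2,True
TEL,H,100.3,2.7,3.1,115.1,8.4,113.0,7.1,2.2,14.6,-7.2,6.3,True
TEL,M,97.9,3.8,8.0,118.7,17.6,120.0,7.8,-1.6,12.7,-4.9,8.5,True
TEL,L,103.0,22.9,27.4,134.1,34.3,149.8,31.2,-9.6,24.9,-4.6,22.1,True
AML,H,93.7,3.7,7.4,96.3,3.0,88.9,2.0,8.3,1.2,4.7,2.5,True
AML,M,94.6,6.5,7.3,105.0,6.3,102.4,20.0,13.8,13.7,11.8,2.4,False
AML,L,73.2,35.1,32.9,94.0,10.0,101.1,19.3,-6.2,9.4,-16.8,11.3,True
RAM,H,101.9,2.3,2.2,85.1,6.5,92.8,4.9,-8.4,5.8,-13.6,14.7,True
RAM,M,105.1,0.9,0.9,87.0,6.1,94.4,3.0,-7.9,6.1,-9.4,10.1,True
RAM,L,90.0,2.7,4.2,89.5,3.3,99.6,8.6,-9.7,8.6,-6.3,13.9,True
RAM-M,H,101.6,2.3,3.5,94.9,2.2,95.2,4.9,-0.1,5.9,-4.7,6.7,True
RAM-M,M,101.2,3.6,3.0,96.1,7.2,94.8,8.6,1.7,7.6,-2.1,9.3,True
RAM-M,L,78.1,4.7,5.1,108.5,18.2,96.8,12.3,11.9,12.6,7.6,12.1,True
NBV,H,89.1,3.2,10.6,102.3,2.9,99.8,5.0,2.6,2.2,-1.4,3.3,True
NBV,M,62.2,6.3,12.0,112.6,4.2,110.5,8.4,2.5,12.5,-1.7,12,True
NBV,L,51.7,4.2,10.0,108.6,0.4,95.9,14.3,14.4,14.8,13.5,15.0,True
NFD,H,109.9,7.2,8.7,102.6,1.7,124.7,4.4,-17.7,2.7,-20.5,4.1,True
NFD,M,108.2,5.7,5.4,99.4,4.3,123.1,4.7,-19.1,8.9,-19.5,20.1,True
NFD,L,100.3,10.8,10.4,118.5,11.0,125.0,15.6,-4.8,4.7,-11.2,9.7,True
SCB,H,100.4,2,2.2,93.8,2.9,100.4,2.7,-6.5,1.2,-9.3,1.4,True
SCB,M,101.6,0.6,0.5,64.9,1.9,98.1,2.5,-3.3,2.4,-5.7,3.6,False
SCB,L,113.6,1.2,1.4,96.7,4.3,97.5,5.9,-0.7,4.6,-2.8,2.8,True
SCB-M,H,93.4,1.2,1.8,92.5,1.6,97.0,1.0,-4.6,1.2,-7.8,2.3,True
SCB-M,M,110.1,0.3,0.5,87.8,2.1,93.9,2.0,-6.5,3.4,-9.2,3.9,True
SCB-M,L,107.2,1.8,1.9,89.3,7.1,95.2,6.0,-6.3,8.3,-9.9,6.5,True
IDP,H,97.8,2.1,1.7,79.5,5.6,88.3,5.9,-9.9,6.5,-14.7,7.2,True
IDP,M,113.4,2.6,2.5,78.6,7.4,90.4,6.6,-13.0,8.5,-17.3,9.0,True
IDP,L,110.4,5.6,5.7,84.9,10.9,99.6,14.8,-13.6,13.7,-16.1,13.0,True
VAL,H,99.0,3.2,2.7,91.7,1.3,96.5,0.7,-5.0,0.9,-14.9,11.1,True
VAL,M,110.0,1.5,1.9,91.0,2.9,95.1,1.2,-4.2,3.4,-8.5,10.9,True
VAL,L,89.6,1.2,2.0,92.4,4.3,94.7,4.2,-2.4,3.9,-1.4,13.9,True
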