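compound,condition,formula,observed_mz,calc_mz,reported_ppm,is_molecular_ion
VOR,none,C18H23N2S,299.1961,299.1981,-6.68,1
VOR,none,C6H5S,109.0364,109.0368,-3.67,0
VOR,none,C8H10N,120.1021,120.1011,8.32,0
VOR,none,C8H8NS,150.0665,150.0659,3.99,0
VOR,none,C16H18NS,256.1512,256.1508,1.56,0
DP1,photolytic,C10H15N2O,179.1172,179.1181,-5.02,1
DP1,photolytic,C2H6N,44.0503,44.05017,2.95,0
DP1,photolytic,C4H8N,70.0659,70.0663,-5.71,0
DP1,photolytic,C4H9N2,85.0747,85.0742,5.88,0
DP1,photolytic,C6H6N,92.0488,92.0493,-5.43,0
DP1,photolytic,C7H8N,106.0645,106.0651,-5.66,0
DP1,photolytic,C7H6NO,108.0441,108.0448,-6.48,0
DP1,photolytic,C8H8N,118.066,118.0658,1.69,0
DP1,photolytic,C8H10NO,136.0763,136.0759,2.94,0
DP2,photolytic,C10H15N2,163.153,163.1541,-6.74,1
DP2,photolytic,C2H6N,44.0659,44.0658,2.26,0
DP2,photolytic,C6H5,77.0616,77.0608,10.38,0
DP2,photolytic,C7H8N,106.0909,106.0914,-4.71,0
DP2,photolytic,C8H8N,118.0851,118.0856,-4.23,0
DP2,photolytic,C8H10N,120.1052,120.1054,-1.66,0
DP2,photolytic,C10H12N,146.0786,146.0791,-3.42,0
DP3,oxidative/photolytic,C18H23N2OS,315.1308,315.1317,-2.86,1
DP3,oxidative/photolytic,C2H6N,44.0673,44.0668,11.35,0
DP3,oxidative/photolytic,C3H6N,56.0697,56.0694,5.35,0
DP3,oxidative/photolytic,C4H10N,72.0678,72.0683,-6.94,0
DP3,oxidative/photolytic,C6H8N,94.091,94.0915,-5.31,0
DP3,oxidative/photolytic,C7H8N,106.0929,106.0923,5.65,0
DP3,oxidative/photolytic,C8H10N,120.1103,120.1107,-3.33,0
DP3,oxidative/photolytic,C7H6NS,136.0531,136.0535,-2.94,0
DP3,oxidative/photolytic,C7H8NS,138.0118,138.0121,-2.17,0
DP3,oxidative/photolytic,C8H6NS,148.0555,148.0554,0.67,0
DP3,oxidative/photolytic,C9H8NS,162.0729,162.0731,-1.23,0
DP3,oxidative/photolytic,C10H11N2S,191.0128,191.0134,-3.14,0
DP3,oxidative/photolytic,C10H13N2OS,209.116,209.1164,-1.91,0
DP3,oxidative/photolytic,C15H16NS,242.1397,242.1391,2.48,0
DP3,oxidative/photolytic,C16H18NS,256.1594,256.1598,-1.56,0
DP4,photolytic,C18H23N2O3S,347.1119,347.1121,-0.58,1
DP4,photolytic,C2H6N,44.066,44.0663,-6.81,0
DP4,photolytic,C3H6N,56.0682,56.0679,5.35,0
DP4,photolytic,C4H8N,70.086,70.0867,-9.99,0
DP4,photolytic,C4H9N2,85.0375,85.0371,4.7,0
DP4,photolytic,C7H7N,105.0971,105.0978,-6.66,0
DP4,photolytic,C7H6NS,136.0504,136.0507,-2.2,0
DP4,photolytic,C16H18NO3S,304.0676,304.0681,-1.64,0
DP5,oxidative,C18H23N2O2S,331.106,331.1064,-1.21,1
DP5,oxidative,C2H6N,44.0652,44.0647,11.35,0
DP5,oxidative,C4H15N,77.7323,77.7326,-3.86,0
DP5,oxidative,C7H7,91.0793,91.0798,-5.49,0
DP5,oxidative,C7H8N,106.0926,106.0931,-4.71,0
DP5,oxidative,C8H9N,119.1755,119.1758,-2.52,0
DP5,oxidative,C7H6NS,136.0527,136.0533,-4.41,0
DP5,oxidative,C6H6NOS,140.0436,140.0441,-3.57,0
DP5,oxidative,C9H8NS,162.3383,162.3389,-3.7,0
DP5,oxidative,C9H8NOS,178.0349,178.0344,2.81,0
DP5,oxidative,C10H10N2S,190.0881,190.0876,2.63,0
DP5,oxidative,C16H18N2O2S,288.1306,288.1311,-1.73,0
DP6,photolytic,C18H23N2O3S,347.1125,347.1121,1.15,1
DP6,photolytic,C3H6N,56.0674,56.0678,-7.13,0
DP6,photolytic,C4H8N,70.1192,70.1197,-7.13,0
DP6,photolytic,C4H8N2,84.3469,84.3473,-4.74,0
DP6,photolytic,C7H8N,106.0865,106.0868,-2.83,0
DP6,photolytic,C8H10N,120.3363,120.3357,4.99,0
DP6,photolytic,C7H4NS,134.0822,134.0828,-4.47,0
DP6,photolytic,C8H5NS,149.1328,149.1317,7.38,0
DP6,photolytic,C8H6NOS,164.1592,164.1597,-3.05,0
DP6,photolytic,C10H9N2OS,205.0757,205.0763,-2.93,0
DP6,photolytic,C10H11N2O2S,223.0854,223.0862,-3.59,0
DP6,photolytic,C16H18NO3S,304.101,304.1015,-1.64,0
DP7,oxidative,C18H23N2OS,315.1527,315.1517,3.17,1
DP7,oxidative,C4H12N,74.0845,74.0841,5.4,0
DP7,oxidative,C7H8N,106.1101,106.1108,-6.6,0
DP7,oxidative,C8H10N,120.1047,120.1053,-5.0,0
DP7,oxidative,C7H6NS,136.0417,136.0422,-3.67,0
DP7,oxidative,C10H11N2S,191.0902,191.0907,-2.62,0
DP7,oxidative,C16H18NS,256.2938,256.2942,-1.56,0
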