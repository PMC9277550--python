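compound,compound_class,retention_index,mean_A,sd_A,mean_B,sd_B,mean_C,sd_C,mean_D,sd_D,mean_E,sd_E,mean_F,sd_F,threshold,oav_band
Ethyl acetate,ester,612,744.07,0.58,3216.51,152.25,1968.87,117.83,1576.59,124.87,1997.31,191.85,3170.56,324.2,7750,0.1-1
Isoamyl acetate,ester,876,Nd,,145.62,3.83,296.36,0.61,142.94,9.15,158.39,5.93,19.14,2.20,30,0.1-1
Pentyl acetate,ester,911,Nd,,Nd,,Nd,,Nd,,Nd,,12.09,0.77,43,0.1-1
Ethyl hexanoate,ester,1000,Nd,,31.42,0.83,133.51,2.34,114.04,2.86,160.72,6.87,71.25,0.88,5,>1
Hexyl acetate,ester,1011,44.12,0.63,995.05,3.13,635.89,25.22,318.01,12.73,238.37,5.92,60.26,0.89,670,<0.1
3-Hexen-1-yl acetate,ester,1005,132.04,22.66,21.67,0.72,10.14,0.01,120.56,6.05,96.22,0.16,24.37,0.26,13,>1
Ethyl lactate,ester,815,Nd,,Nd,,176.19,0.13,256.21,2.27,397.98,4.23,262.76,9.02,154636,<0.1
Isoamyl lactate,ester,1047,Nd,,1.37,0.04,12.17,0.83,15.51,0.2,24.68,1.9,21.05,1.45,/,
3-Hexenyl isobutyrate,ester,1145,13.69,1.53,0,0,Nd,,Nd,,Nd,,Nd,,/,
2-Hexen-1-ol acetate,ester,1006,105.4,0.78,56.21,4.23,26.86,0.45,3.31,0.22,Nd,,Nd,,/,
Ethyl caprylate,ester,1196,8.97,0.26,24.86,0.26,235.17,3.66,33.3,2.33,245.67,4.01,190.71,7.57,5,>1
Ethyl non-anoate,ester,1296,3.41,0.15,1.69,0.31,40.99,0.7,138.45,2.44,29.94,1.37,29.09,2.89,1300,<0.1
Ethyl caprate,ester,1396,2.74,0.01,53.55,0,355.53,10.98,10.02,0.01,357.58,5.36,225.95,18.35,200,>1
Ethyl benzoate,ester,1171,11.63,0.47,23.99,2.57,15.4,0.28,15.07,0.05,20.08,0.76,934.12,24.13,53,>1
Ethyl phenylacetate,ester,1246,Nd,,3.17,0.05,2.67,0.12,4.57,0.4,6.97,0.69,Nd,,155.5,<0.1
Ethyl laurate,ester,1595,Nd,,Nd,,15.1,0.07,46.96,4.92,49.88,1.33,26.33,0.94,500,<0.1
Phenethyl acetate,ester,1258,329.44,2.99,752.9,2.33,3985.34,272.48,3505.94,4.2,3406.42,66.17,2514.08,9.96,1800,>1
Ethyl tetradecanoate,ester,1794,Nd,,Nd,,1.23,0.01,2.77,0.54,2.43,0.02,7.44,0.31,2000,<0.1
γ-Decalactone,ester,1470,434.39,45.81,375.85,30.84,152.88,2.04,84.94,3.49,154.7,3.32,110.02,7.09,1.1,>1
Ethyl palmitate,ester,1993,Nd,,Nd,,2.71,0.5,15.39,2.4,8.05,0.04,17.06,0.75,1000,<0.1
Tetradecalactone,ester,1935,Nd,,Nd,,Nd,,Nd,,17.73,0.23,13.28,0.15,29,0.1-1
γ-Dodecalactone,ester,1678,10.09,1.62,4.02,0.85,4.45,0.32,4.27,0.19,9.17,0.04,6.09,0.06,0.43,>1
Methyl benzoate,ester,1094,6.67,0.08,40.12,0.01,367.72,5.46,502.98,9.18,823.4,16.55,20.58,1.82,73,0.1-1
Ethanol,alcohol,324,Nd,,986.83,47.26,2398.01,140.01,2196.84,139.8,886.33,61.04,233,8.49,950,>1
3-Methyl-1-butanol,alcohol,736,Nd,,126.23,18.55,791.3,7.99,1111.01,78.5,1309.73,77.59,874.02,2.84,7000,0.1-1
1-Hexanol,alcohol,868,Nd,,1221.71,1.21,830.23,14.3,731.61,22.35,843.07,4.9,533.48,9.53,5200,0.1-1
3-Hexen-1-ol,alcohol,852,186.32,21.46,162.09,8.55,105.73,4.76,85.51,0.36,112.82,1.99,96.68,4.72,400,0.1-1
Cyclohexanol,alcohol,880,576.53,0.12,356.79,26.01,Nd,,Nd,,Nd,,Nd,,300,
2-Octanol,alcohol,998,Nd,,Nd,,Nd,,5.93,0.66,4.8,0.57,Nd,,120,
Cyclohexanemethanol,alcohol,/,103.76,2.48,Nd,,Nd,,Nd,,Nd,,Nd,,/,
1-Octanol,alcohol,1071,Nd,,18.98,1.36,14.96,2.13,4.26,0.12,21.37,2.87,Nd,,800,
"2,3-Butanediol",alcohol,1071,Nd,,18.98,2.81,14.96,0.47,4.26,0.54,21.37,2.38,Nd,,800,
2-Non-anol,alcohol,/,Nd,,2.7,0.49,8.9,0.64,83.75,2.65,15.79,0.56,143.46,9.52,20-50,>1
Benzyl alcohol,alcohol,1173,Nd,,68.24,12.9,Nd,,Nd,,Nd,,Nd,,600,
Phenylethyl alcohol,alcohol,1036,12.29,0.03,584.32,59.62,422.52,1.78,284.16,17.08,506.31,11.53,287.62,5.39,20000,<0.1
β-ionol,alcohol,1116,8.7,0.3,170.91,43.07,583.62,2.56,492.85,9.09,1061.17,43.96,869,48.79,10000,<0.1
Hexanal,aldehyde,800,221.18,0.69,5.03,1.44,Nd,,Nd,,Nd,,Nd,,5-15,
2-Hexenal,aldehyde,851,1070.62,3.83,Nd,,Nd,,Nd,,Nd,,Nd,,30,
"2,4-Heptadienal",aldehyde,1012,2.91,0.29,Nd,,Nd,,Nd,,Nd,,Nd,,15.4,
Benzaldehyde,aldehyde,962,4.23,0.02,256.52,18.75,384.66,21.68,238.98,6.35,164.84,3.42,133.46,2.45,2000,<0.1
"2,5-Dimethylbenzaldehyde",aldehyde,1208,56.73,0.34,85.65,4,135.94,11.27,282.24,15.73,245.35,0.25,347.97,5.64,200,>1
4-Undecanolide,aldehyde,1576,Nd,,Nd,,2.03,0.02,1.98,0.34,1.87,0.01,Nd,,2.1,0.1-1
3-Octanone,ketone,986,10.85,0.48,10.87,0.62,4.56,0.4,1.79,0.56,Nd,,Nd,,21.4,
Geranylacetone,ketone,1453,Nd,,Nd,,Nd,,Nd,,8.4,0,9.83,0.59,60,0.1-1
Linalool,terpene,1099,22.68,0.02,45.21,0.15,72.71,8.99,67.71,1.92,113.95,10.57,Nd,,25,
β-Ionone,terpene,1491,3.93,0.9,18.62,0.44,19.23,0.16,20.23,1.58,23.54,0.38,25.28,4.44,8.4,>1
Geraniol,terpene,1255,Nd,,Nd,,Nd,,6.32,0.23,16.28,0.91,8.09,0.06,0.99,>1
Eugenol,phenol,1357,0.28,0.01,32.7,1.91,152.03,29.72,111.6,1.13,125.2,10.75,136.87,19,5,>1
1-Hexanoic acid,acid,990,10.11,0.79,463.64,45,122.07,14.9,55.1,3.61,112.97,9.17,66.41,4.53,420,0.1-1
Octanoic acid,acid,1180,1.3,0.05,62.56,0.4,75.29,1.92,43.78,1.26,116.29,4.45,41.37,0.97,500,<0.1
Non-anoic acid,acid,1273,Nd,,Nd,,5.09,0.06,2.97,0.69,12.89,2.04,6.47,0.05,500-800,<0.1
Decanoic acid,acid,1373,Nd,,13.36,0.96,22.6,1.84,23.42,2.42,50.69,7.56,15.52,1.07,1000,<0.1
Benzoic acid,acid,1170,Nd,,Nd,,15.2,0.14,304.25,31.89,826.66,54.21,Nd,,1000,
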