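subject,scheme,species,region,mean_mM,sd_mM
1,bSSFP,glc,GM,2.79,0.89
1,spoiledFID,glc,GM,2.85,0.97
1,bSSFP,glx,GM,4.57,2.41
1,spoiledFID,glx,GM,4.76,1.75
1,bSSFP,glx,WM,3.68,1.40
1,spoiledFID,glx,WM,3.13,1.01
1,bSSFP,glc,WM,2.16,0.35
1,spoiledFID,glc,WM,2.29,0.77
1,bSSFP,water,GM,16.51,2.84
1,spoiledFID,water,GM,15.97,2.55
1,bSSFP,water,WM,13.40,1.48
1,spoiledFID,water,WM,13.01,1.63
2,bSSFP,glc,GM,2.19,0.79
2,spoiledFID,glc,GM,1.74,0.65
2,bSSFP,glx,GM,3.46,1.63
2,spoiledFID,glx,GM,2.84,1.12
2,bSSFP,glx,WM,2.39,0.83
2,spoiledFID,glx,WM,2.01,0.64
2,bSSFP,glc,WM,1.71,0.45
2,spoiledFID,glc,WM,1.43,0.55
2,bSSFP,water,GM,15.35,1.78
2,spoiledFID,water,GM,15.27,1.76
2,bSSFP,water,WM,12.91,1.05
2,spoiledFID,water,WM,12.81,1.04
3,bSSFP,glc,GM,4.94,1.65
3,spoiledFID,glc,GM,4.55,1.16
3,bSSFP,glx,GM,5.05,2.37
3,spoiledFID,glx,GM,3.94,1.79
3,bSSFP,glx,WM,3.95,1.49
3,spoiledFID,glx,WM,2.46,1.08
3,bSSFP,glc,WM,3.27,0.65
3,spoiledFID,glc,WM,3.89,1.09
3,bSSFP,water,GM,18.48,3.99
3,spoiledFID,water,GM,14.43,3.27
3,bSSFP,water,WM,12.65,1.91
3,spoiledFID,water,WM,11.50,2.37
4,bSSFP,glc,GM,2.90,1.04
4,spoiledFID,glc,GM,3.00,1.02
4,bSSFP,glx,GM,4.85,2.06
4,spoiledFID,glx,GM,3.74,1.40
4,bSSFP,glx,WM,3.41,1.27
4,spoiledFID,glx,WM,2.58,0.84
4,bSSFP,glc,WM,2.56,0.66
4,spoiledFID,glc,WM,2.53,0.62
4,bSSFP,water,GM,16.58,3.38
4,spoiledFID,water,GM,15.54,3.25
4,bSSFP,water,WM,13.62,2.38
4,spoiledFID,water,WM,12.52,1.38
5,bSSFP,glc,GM,3.23,0.88
5,spoiledFID,glc,GM,3.82,1.04
5,bSSFP,glx,GM,2.76,1.42
5,spoiledFID,glx,GM,2.85,1.49
5,bSSFP,glx,WM,2.27,0.94
5,spoiledFID,glx,WM,1.95,0.93
5,bSSFP,glc,WM,2.56,0.46
5,spoiledFID,glc,WM,2.98,0.55
5,bSSFP,water,GM,16.65,2.89
5,spoiledFID,water,GM,15.34,2.85
5,bSSFP,water,WM,13.18,1.75
5,spoiledFID,water,WM,12.61,1.36
6,bSSFP,glc,GM,1.38,0.85
6,spoiledFID,glc,GM,1.77,0.94
6,bSSFP,glx,GM,3.64,2.13
6,spoiledFID,glx,GM,2.40,1.19
6,bSSFP,glx,WM,2.60,1.24
6,spoiledFID,glx,WM,1.62,0.85
6,bSSFP,glc,WM,1.06,0.47
6,spoiledFID,glc,WM,1.37,0.37
6,bSSFP,water,GM,13.21,3.67
6,spoiledFID,water,GM,14.52,5.31
6,bSSFP,water,WM,10.49,2.31
6,spoiledFID,water,WM,12.31,1.65
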