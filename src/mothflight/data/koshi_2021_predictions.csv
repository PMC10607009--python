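# Daily migration predictions at the Koshi trap site, May 2021.
# date: prediction-row date (JST); predicted: Y/N; source: province code of the
# earliest predicted arrival (ZJ Zhejiang, FJ Fujian, GD Guangdong, JX Jiangxi,
# TW Taiwan); ft_h: flight time in whole hours from the 10:00 UTC take-off.
date,predicted,source,ft_h
2021-05-01,Y,ZJ,12
2021-05-02,N,,
2021-05-03,N,,
2021-05-04,Y,JX,38
2021-05-05,N,,
2021-05-06,Y,TW,35
2021-05-07,Y,ZJ,29
2021-05-08,Y,ZJ,23
2021-05-09,Y,ZJ,37
2021-05-10,Y,FJ,36
2021-05-11,N,,
2021-05-12,Y,JX,35
2021-05-13,Y,FJ,29
2021-05-14,Y,FJ,32
2021-05-15,Y,ZJ,20
2021-05-16,Y,TW,20
2021-05-17,N,,
2021-05-18,N,,
2021-05-19,Y,ZJ,30
2021-05-20,Y,TW,20
2021-05-21,N,,
2021-05-22,N,,
2021-05-23,Y,TW,36
2021-05-24,N,,
2021-05-25,N,,
2021-05-26,Y,ZJ,11
2021-05-27,N,,
2021-05-28,Y,ZJ,23
2021-05-29,N,,
2021-05-30,N,,
2021-05-31,N,,
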