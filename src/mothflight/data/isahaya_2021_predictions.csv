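# Daily migration predictions at the Isahaya trap site, May 2021.
# Columns as in koshi_2021_predictions.csv.
date,predicted,source,ft_h
2021-05-01,Y,ZJ,11
2021-05-02,N,,
2021-05-03,N,,
2021-05-04,Y,GD,35
2021-05-05,N,,
2021-05-06,Y,TW,33
2021-05-07,Y,ZJ,24
2021-05-08,Y,ZJ,21
2021-05-09,Y,ZJ,32
2021-05-10,Y,FJ,34
2021-05-11,N,,
2021-05-12,Y,ZJ,26
2021-05-13,Y,FJ,27
2021-05-14,Y,FJ,29
2021-05-15,Y,ZJ,17
2021-05-16,Y,TW,18
2021-05-17,N,,
2021-05-18,N,,
2021-05-19,Y,FJ,31
2021-05-20,Y,GD,32
2021-05-21,N,,
2021-05-22,N,,
2021-05-23,Y,ZJ,36
2021-05-24,N,,
2021-05-25,N,,
2021-05-26,Y,TW,30
2021-05-27,N,,
2021-05-28,Y,ZJ,20
2021-05-29,N,,
2021-05-30,N,,
2021-05-31,N,,
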