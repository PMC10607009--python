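# Daily pheromone-trap catches at Koshi, May 2021 (collections performed daily).
collection_date,count,interval_days
2021-05-01,0,1
2021-05-02,34,1
2021-05-03,38,1
2021-05-04,18,1
2021-05-05,9,1
2021-05-06,17,1
2021-05-07,22,1
2021-05-08,3,1
2021-05-09,9,1
2021-05-10,13,1
2021-05-11,0,1
2021-05-12,2,1
2021-05-13,3,1
2021-05-14,1,1
2021-05-15,0,1
2021-05-16,0,1
2021-05-17,0,1
2021-05-18,0,1
2021-05-19,1,1
2021-05-20,0,1
2021-05-21,0,1
2021-05-22,3,1
2021-05-23,0,1
2021-05-24,1,1
2021-05-25,0,1
2021-05-26,0,1
2021-05-27,0,1
2021-05-28,0,1
2021-05-29,0,1
2021-05-30,0,1
2021-05-31,1,1
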