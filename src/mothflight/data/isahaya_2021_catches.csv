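# Pheromone-trap catches at Isahaya, May 2021. Collections were daily or at
# 2-5-day intervals; interval_days states how many days (ending on the
# collection date) each collection covers. The interval lengths are inferred
# from the gaps between published collection dates and are therefore partly
# reconstructed; no collection covering 31 May is available in the published
# record (it presumably ran into June).
collection_date,count,interval_days
2021-05-01,0,1
2021-05-05,0,4
2021-05-07,0,2
2021-05-12,0,5
2021-05-17,7,5
2021-05-18,0,1
2021-05-19,0,1
2021-05-20,2,1
2021-05-21,19,1
2021-05-22,3,1
2021-05-23,2,1
2021-05-24,3,1
2021-05-25,7,1
2021-05-27,2,2
2021-05-28,0,1
2021-05-29,3,1
2021-05-30,0,1
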