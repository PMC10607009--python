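# Published per-day hit/fail/excluded marks for Koshi, May 2021, for the 3-day
# and 5-day evaluation windows (H = hit, F = fail, - = excluded).
date,mark_3day,mark_5day
2021-05-01,H,H
2021-05-02,-,-
2021-05-03,-,-
2021-05-04,H,H
2021-05-05,-,-
2021-05-06,H,H
2021-05-07,H,H
2021-05-08,H,H
2021-05-09,H,H
2021-05-10,H,H
2021-05-11,-,-
2021-05-12,H,H
2021-05-13,H,H
2021-05-14,F,H
2021-05-15,F,H
2021-05-16,H,H
2021-05-17,-,-
2021-05-18,-,-
2021-05-19,H,H
2021-05-20,H,H
2021-05-21,-,-
2021-05-22,-,-
2021-05-23,H,H
2021-05-24,-,-
2021-05-25,-,-
2021-05-26,F,F
2021-05-27,-,-
2021-05-28,H,H
2021-05-29,-,-
2021-05-30,-,-
2021-05-31,F,-
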