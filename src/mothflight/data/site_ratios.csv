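# Published per-site hitting ratios of the two-year trap verification
# (six sites per year; Izumo was replaced by Nagakute during 2021 but the
# published ratio matrix keeps the label Izumo for that row — kept verbatim).
year,site,ratio_3day,ratio_5day
2020,Minami-satsuma,0.67,0.88
2020,Koshi,0.76,0.93
2020,Isahaya,0.89,0.89
2020,Nangoku,0.64,0.81
2020,Izumo,0.83,0.76
2020,Towada,0.96,0.95
2021,Minami-satsuma,0.83,1.00
2021,Koshi,0.78,0.94
2021,Isahaya,0.44,0.59
2021,Nangoku,0.79,0.87
2021,Izumo,0.84,0.75
2021,Towada,0.91,0.95
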