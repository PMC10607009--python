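# Pheromone-trap catalog used for prediction verification (2020 and 2021 surveys).
# The Izumo trap survey ended during the period and was replaced by Nagakute in 2021.
year,name,lat,lon
2020,Minami-satsuma,31.48,130.34
2020,Koshi,32.88,130.74
2020,Isahaya,32.83,130.02
2020,Nangoku,33.59,133.64
2020,Izumo,35.33,132.75
2020,Towada,40.62,141.16
2021,Minami-satsuma,31.48,130.34
2021,Koshi,32.88,130.74
2021,Isahaya,32.83,130.02
2021,Nangoku,33.59,133.64
2021,Nagakute,35.16,137.08
2021,Towada,40.62,141.16
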