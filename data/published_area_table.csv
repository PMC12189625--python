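species,scenario,period,present_area_1e3_km2,future_area_1e3_km2,printed_trend_percent
S. horneri,SSP1-1.9,2030s,14.40,10.33,-28.25
S. horneri,SSP1-1.9,2060s,14.40,9.81,-31.87
S. horneri,SSP1-1.9,2090s,14.40,10.21,-29.12
S. horneri,SSP2-4.5,2030s,14.40,12.40,-13.91
S. horneri,SSP2-4.5,2060s,14.40,6.80,-52.81
S. horneri,SSP2-4.5,2090s,14.40,2.77,-80.78
S. horneri,SSP5-8.5,2030s,14.40,9.62,-33.18
S. horneri,SSP5-8.5,2060s,14.40,2.37,-83.57
S. horneri,SSP5-8.5,2090s,14.40,1.52,-89.42
S. macrocarpum,SSP1-1.9,2030s,6.61,4.34,-34.42
S. macrocarpum,SSP1-1.9,2060s,6.61,3.69,-44.12
S. macrocarpum,SSP1-1.9,2090s,6.61,4.44,-32.89
S. macrocarpum,SSP2-4.5,2030s,6.61,5.46,-17.49
S. macrocarpum,SSP2-4.5,2060s,6.61,2.14,-67.61
S. macrocarpum,SSP2-4.5,2090s,6.61,1.45,-78.00
S. macrocarpum,SSP5-8.5,2030s,6.61,3.62,-45.20
S. macrocarpum,SSP5-8.5,2060s,6.61,1.48,-77.63
S. macrocarpum,SSP5-8.5,2090s,6.61,0.10,-98.45
S. patens,SSP1-1.9,2030s,5.61,6.17,9.91
S. patens,SSP1-1.9,2060s,5.61,5.93,5.78
S. patens,SSP1-1.9,2090s,5.61,6.26,11.66
S. patens,SSP2-4.5,2030s,5.61,6.29,12.14
S. patens,SSP2-4.5,2060s,5.61,4.61,-17.87
S. patens,SSP2-4.5,2090s,5.61,4.69,-16.32
S. patens,SSP5-8.5,2030s,5.61,5.25,-6.51
S. patens,SSP5-8.5,2060s,5.61,4.28,-23.70
S. patens,SSP5-8.5,2090s,5.61,0.90,-83.96
S. piluliferum,SSP1-1.9,2030s,13.85,10.74,-22.49
S. piluliferum,SSP1-1.9,2060s,13.85,12.04,-13.09
S. piluliferum,SSP1-1.9,2090s,13.85,9.73,-29.80
S. piluliferum,SSP2-4.5,2030s,13.85,13.04,-5.78
S. piluliferum,SSP2-4.5,2060s,13.85,12.15,-12.27
S. piluliferum,SSP2-4.5,2090s,13.85,11.37,-17.94
S. piluliferum,SSP5-8.5,2030s,13.85,14.12,1.93
S. piluliferum,SSP5-8.5,2060s,13.85,16.98,22.58
S. piluliferum,SSP5-8.5,2090s,13.85,18.19,31.29
Total,SSP1-1.9,2030s,16.92,14.12,-16.5
Total,SSP1-1.9,2060s,16.92,15.08,-10.8
Total,SSP1-1.9,2090s,16.92,13.69,-19.0
Total,SSP2-4.5,2030s,16.92,15.83,-6.4
Total,SSP2-4.5,2060s,16.92,14.71,-13.0
Total,SSP2-4.5,2090s,16.92,14.11,-16.5
Total,SSP5-8.5,2030s,16.92,15.62,-7.6
Total,SSP5-8.5,2060s,16.92,18.06,6.7
Total,SSP5-8.5,2090s,16.92,19.07,12.5
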