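class,grassland,urban,cropland,forest,water,barren,sum
grassland,1674080.00,621.07,4410.37,12466.30,2512.63,51465.50,1745555.87
urban,20.20,342.98,19.65,18.95,0.00,93.71,495.48
cropland,5194.98,231.40,65535.90,1241.25,11.18,568.94,72783.66
forest,12062.90,134.19,1780.98,278227.00,69.71,468.88,292743.65
water,394.48,1.24,58.10,285.74,44509.60,1652.62,46901.79
barren,35882.40,77.79,290.11,1774.93,1429.83,513061.00,552516.05
sum,1727634.96,1408.66,72095.10,294014.18,48532.95,567310.65,2710996.50
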