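city,country,population,max_si,no2_deaths,no2_lo95,no2_hi95,o3_deaths,o3_lo95,o3_hi95,pm25_deaths,pm25_lo95,pm25_hi95,pm10_deaths,pm10_lo95,pm10_hi95
Amsterdam,Netherlands,1128715,79.63,-5.90,-7.20,-4.60,0.80,0.60,1.10,-1.80,-2.10,-1.60,-1.40,-1.50,-1.20
Ankara,Turkey,3002440,77.78,-8.30,-10.10,-6.50,-1.30,-1.70,-0.90,-0.60,-0.70,-0.50,-0.70,-0.80,-0.60
Athens,Greece,3315199,84.26,-40.10,-48.80,-31.20,-0.70,-1.00,-0.50,-10.00,-11.40,-8.80,-7.80,-8.70,-6.90
Barcelona,Spain,3832012,85.19,-39.20,-47.70,-30.50,-1.20,-1.60,-0.80,-12.20,-13.90,-10.70,-9.30,-10.30,-8.30
Belgrade,Serbia,1106870,100.00,-1.60,-2.00,-1.30,-2.50,-3.20,-1.70,-1.40,-1.60,-1.20,-1.00,-1.20,-0.90
Berlin,Germany,3271872,76.85,-9.60,-11.60,-7.40,-1.60,-2.10,-1.10,-4.70,-5.40,-4.10,-3.50,-3.80,-3.10
Bern,Switzerland,197760,73.15,-0.50,-0.60,-0.40,-0.30,-0.50,-0.20,-0.50,-0.60,-0.40,-0.40,-0.40,-0.30
Birmingham,United Kingdom,2426863,75.93,-8.90,-10.80,-6.90,1.00,0.70,1.30,-4.20,-4.80,-3.70,-3.10,-3.50,-2.80
Bratislava,Slovakia,352002,87.04,-1.00,-1.20,-0.80,-0.40,-0.60,-0.30,-0.50,-0.60,-0.40,-0.40,-0.40,-0.30
Brussels,Belgium,1381517,81.48,-10.40,-12.70,-8.10,1.40,0.90,1.80,-3.20,-3.70,-2.80,-2.40,-2.70,-2.10
Bucharest,Romania,1774128,87.04,-9.50,-11.50,-7.40,-2.40,-3.20,-1.70,-2.80,-3.10,-2.40,-2.20,-2.40,-1.90
Budapest,Hungary,1758468,76.85,-7.30,-8.90,-5.70,-2.90,-3.90,-2.00,-2.80,-3.20,-2.40,-2.30,-2.50,-2.00
Cologne,Germany,1508677,76.85,-10.10,-12.30,-7.80,0.60,0.40,0.80,-4.40,-5.00,-3.80,-3.20,-3.60,-2.90
Copenhagen,Denmark,1225959,72.22,-4.50,-5.50,-3.50,0.50,0.40,0.70,-1.20,-1.40,-1.10,-1.00,-1.10,-0.90
Dublin,Ireland,1004263,90.74,-3.30,-4.00,-2.60,0.30,0.20,0.40,-1.00,-1.20,-0.90,-0.80,-0.90,-0.70
Hamburg,Germany,1596992,76.85,-7.30,-8.90,-5.70,0.30,0.20,0.40,-2.40,-2.80,-2.10,-1.90,-2.10,-1.70
Helsinki,Finland,907386,60.19,-1.90,-2.30,-1.50,0.10,0.10,0.10,-0.50,-0.60,-0.40,-0.70,-0.80,-0.70
Lisbon,Portugal,1958521,87.96,-18.90,-23.00,-14.70,0.30,0.20,0.40,-11.40,-13.10,-10.00,-10.60,-11.80,-9.40
Ljubljana,Slovenia,250335,89.81,-0.70,-0.80,-0.50,-0.40,-0.60,-0.30,-0.40,-0.50,-0.40,-0.30,-0.30,-0.30
London,United Kingdom,9609627,75.93,-37.90,-46.10,-29.50,4.90,3.40,6.50,-13.90,-15.80,-12.20,-10.50,-11.70,-9.30
Luxembourg,Luxembourg,119160,79.63,-0.40,-0.40,-0.30,-0.10,-0.10,-0.10,-0.20,-0.30,-0.20,-0.20,-0.20,-0.20
Lyon,France,1152368,87.96,-6.70,-8.20,-5.20,-1.00,-1.30,-0.70,-2.60,-3.00,-2.30,-2.00,-2.20,-1.80
Madrid,Spain,4894295,85.19,-38.80,-47.20,-30.20,-3.40,-4.50,-2.30,-7.70,-8.70,-6.70,-6.10,-6.70,-5.40
Marseille,France,909727,87.96,-3.20,-3.80,-2.50,-1.50,-1.90,-1.00,-1.70,-1.90,-1.50,-1.30,-1.40,-1.10
Milan,Italy,3011030,93.52,-36.70,-44.70,-28.60,-6.10,-8.00,-4.10,-18.10,-20.60,-15.80,-12.60,-14.00,-11.20
Monaco,France,59433,87.96,-0.20,-0.20,-0.10,-0.20,-0.20,-0.10,-0.10,-0.20,-0.10,-0.10,-0.10,-0.10
Munich,Germany,1573652,76.85,-5.50,-6.70,-4.30,-1.50,-1.90,-1.00,-3.10,-3.50,-2.70,-2.30,-2.50,-2.00
Naples,Italy,3167668,93.52,-29.90,-36.40,-23.30,-1.90,-2.60,-1.30,-8.20,-9.40,-7.20,-5.90,-6.50,-5.20
Nicosia,Cyprus,228923,94.44,-0.30,-0.40,-0.20,-0.30,-0.40,-0.20,-0.20,-0.20,-0.10,-0.10,-0.10,-0.10
Oslo,Norway,782172,79.63,-0.70,-0.90,-0.60,-0.10,-0.10,-0.00,-0.20,-0.20,-0.20,-0.20,-0.20,-0.10
Paris,France,9711652,87.96,-69.20,-84.20,-53.80,3.50,2.40,4.60,-23.20,-26.50,-20.40,-17.40,-19.30,-15.40
Prague,Czech Republic,1126681,82.41,-2.60,-3.20,-2.10,-1.00,-1.30,-0.70,-1.60,-1.80,-1.40,-1.10,-1.20,-1.00
Pristina,Kosovo,196913,92.59,,,,,,,,,,,,
Reykjavik,Iceland,184357,53.70,-0.10,-0.10,-0.10,0.00,0.00,0.00,-0.00,-0.00,-0.00,-0.00,-0.00,-0.00
Riga,Latvia,556672,65.74,-0.60,-0.80,-0.50,-0.40,-0.50,-0.30,-0.40,-0.40,-0.30,-0.30,-0.30,-0.30
Rome,Italy,2342860,93.52,-18.40,-22.40,-14.30,-5.80,-7.70,-4.00,-6.80,-7.70,-5.90,-4.80,-5.30,-4.30
Sarajevo,Bosnia and Herzegovina,371884,92.59,-0.40,-0.50,-0.30,-0.70,-1.00,-0.50,-0.30,-0.40,-0.30,-0.20,-0.30,-0.20
Sofia,Bulgaria,926881,73.15,-3.50,-4.30,-2.70,-1.40,-1.90,-1.00,-1.10,-1.30,-1.00,-0.80,-0.90,-0.80
Stockholm,Sweden,1305076,46.30,-1.80,-2.20,-1.40,-0.20,-0.30,-0.10,-0.70,-0.80,-0.60,-1.10,-1.20,-0.90
Tallinn,Estonia,344511,77.78,-0.50,-0.70,-0.40,-0.10,-0.10,-0.10,-0.10,-0.20,-0.10,-0.10,-0.10,-0.10
Tirana,Albania,719252,89.81,-1.50,-1.80,-1.10,-0.90,-1.10,-0.60,-0.70,-0.70,-0.60,-0.50,-0.60,-0.40
Turin,Italy,1205385,93.52,-13.30,-16.20,-10.30,-3.60,-4.80,-2.50,-6.80,-7.80,-6.00,-4.90,-5.40,-4.30
Valencia,Spain,1393120,85.19,-8.00,-9.70,-6.20,-1.90,-2.60,-1.30,-3.30,-3.70,-2.90,-2.50,-2.80,-2.20
Vienna,Austria,1856676,85.19,-6.10,-7.40,-4.70,-1.80,-2.40,-1.20,-3.10,-3.50,-2.70,-2.30,-2.50,-2.00
Vilnius,Lithuania,355430,87.04,-0.80,-1.00,-0.60,-0.20,-0.30,-0.10,-0.30,-0.40,-0.30,-0.20,-0.30,-0.20
Warsaw,Poland,1789294,83.33,-7.50,-9.20,-5.90,-1.00,-1.30,-0.70,-2.90,-3.30,-2.50,-2.00,-2.20,-1.80
Zagreb,Croatia,660653,96.30,-1.90,-2.30,-1.40,-1.50,-1.90,-1.00,-1.20,-1.40,-1.10,-1.00,-1.10,-0.90
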