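flight,sensor,tp,fp,fn,precision,recall,f1
1,RGB,260,0,542,100,32.4,48.9
1,Green,142,0,660,100,17.7,30.1
1,Green/Pol,42,3,760,93.3,5.2,9.9
2,RGB,1240,6,722,99.5,63.2,77.3
2,Green,279,0,1683,100,14.2,24.9
2,Green/Pol,39,1,1923,97.5,2.0,3.9
3,RGB,871,8,431,99.1,66.9,79.9
3,Green,142,3,1160,97.9,10.9,19.6
3,Green/Pol,24,14,1278,63.2,1.8,3.6
4,RGB,434,0,17,100,96.2,98.1
4,Green,248,7,203,97.3,55.0,70.3
4,Green/Pol,127,1,324,99.2,28.2,43.9
5,RGB,247,392,305,38.7,44.7,41.5
5,Green,95,234,457,28.9,17.2,21.6
5,Green/Pol,33,95,519,25.8,6.0,9.7
6,RGB,468,3,1871,99.4,20.0,33.3
6,Green,469,8,1870,98.3,20.1,33.3
6,Green/Pol,447,9,1892,98.0,19.1,31.2
7,RGB,1228,1,841,99.9,59.4,74.5
7,Green,679,1,1390,99.9,32.8,49.4
7,Green/Pol,472,7,1597,98.5,22.8,37.0
8,RGB,853,0,198,100,81.2,89.6
8,Green,463,0,588,100,44.1,61.1
8,Green/Pol,673,0,378,100,64.0,78.0
9,RGB,320,6,580,98.2,35.6,52.2
9,Green,58,4,842,93.5,6.4,12.0
9,Green/Pol,235,2,665,99.2,26.1,41.3
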