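,Agriculture,Industry,Construction,TPT,CD,Other services,Final demand,Outflow,Supply sums,Proportion (%)
Agriculture,2.7,-1.5,-0.2,-0.0,-0.3,-1.2,13.2,-1.3,11.4,1.6
Industry,-1.7,21.5,13.8,-9.4,-14.0,-34.4,-19.1,94.6,51.3,7.2
Construction,-0.0,-1.3,-1.5,-1.3,-2.1,-5.6,75.2,7.8,71.3,10.0
TPT,-0.4,-16.0,-2.5,24.4,-2.1,-2.4,6.9,17.6,25.5,3.6
CD,-0.4,-3.5,1.6,-1.9,-3.1,5.4,-3.4,9.3,4.0,0.6
Other services,-1.2,-30.6,-6.6,-11.3,2.2,10.7,112.4,56.4,131.9,18.6
Value added,0.3,-20.4,0.3,25.9,42.4,120.7,0.0,0.0,169.2,23.8
Inflows,11.0,243.1,7.1,4.5,8.3,-28.4,0.0,0.0,245.5,34.6
Demand sums,10.2,191.2,11.9,30.9,31.4,64.8,185.2,184.3,710.0,
Proportion (%),1.4,26.9,1.7,4.3,4.4,9.1,26.1,26.0,,
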