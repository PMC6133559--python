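x,fit1,fit2,fit3,fit4,fit5
  0.493542349431664,0.950368882420777,0.951994366598690,0.952629928100094,0.953292833931311,0.953294203468953
  6.649438537715469,0.960017120861836,0.959689868980496,0.959750896025512,0.959842096352461,0.959825072251322
 12.805334725999273,0.967875209324163,0.966435680575753,0.966105744055002,0.965855688705035,0.965845881954931
 18.961230914283078,0.974049522897251,0.972305197770542,0.971755283177814,0.971359185458618,0.971371481748140
 25.117127102566883,0.978388037842146,0.977324043637204,0.976735590341189,0.976366302690155,0.976408289562232
 31.273023290850688,0.980178164828853,0.981346702065168,0.981025411762245,0.980873850110027,0.980952015843914
 37.428919479134493,0.982982100234292,0.983799225336265,0.984527935300224,0.984864035599980,0.984990134280271
 43.584815667418297,0.986170830456056,0.986644023992852,0.987183045622505,0.988306899500797,0.988503251559846
 49.740711855702102,0.989781138335677,0.990011646370461,0.990477057691061,0.991179534989685,0.991470679741025
 55.896608043985907,0.993192196858645,0.993318128356166,0.993438316261063,0.993637510436272,0.993897187889692
 62.052504232269712,0.996366125478242,0.996302823487764,0.996287135038649,0.996192066909072,0.995996145368359
 68.208400420553517,0.998963884802187,0.999017219310899,0.998670282775086,0.998499911544684,0.997360744038769
 74.364296608837321,1.000452423706140,1.000941935177686,1.000556752119174,0.999767842908140,0.998425976618370
 80.520192797121126,1.001877937138477,1.001537901604248,1.001087713568325,1.000032468360805,0.999227302377905
 86.676088985404931,1.000698306674366,1.000836694279395,1.000596483879941,0.999525078048656,0.999722993996430
 92.831985173688736,0.999093047999797,0.998569554045848,0.998607623559218,0.999373428038371,0.999886308824251
 98.987881361972541,0.997826473849309,0.995896237016011,0.997671604669197,0.999119729918386,0.999703569569338
105.143777550256345,0.993477350237650,0.995480786133784,0.997218255985561,0.998680655656997,0.999173767474088
111.299673738540150,0.997982966414693,0.996890946987573,0.997110393490739,0.998071459596964,0.998305988116354
117.455569926823955,0.998547118806963,0.997724434990129,0.997483438407003,0.997342113140823,0.997117278118013
123.611466115107760,0.996199345145868,0.997945035430834,0.998385819084392,0.996535819246322,0.995625212902159
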