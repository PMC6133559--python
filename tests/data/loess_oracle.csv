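x,y,fit1,fit2,fit3,fit4,fit5
  0.493542349431664,0.949097813081469,0.950368882420777,0.951994366598690,0.952629928100094,0.953292833931311,0.953294203468953
  0.916768360184506,0.951915295677698,0.951090794742093,0.952555351899978,0.953145313527626,0.953760845016006,0.953759896768522
 10.304694762453437,0.963637538491639,0.964893735949530,0.963805140721375,0.963612678840101,0.963475696084911,0.963460582781957
 14.685920206829906,0.972640472550384,0.969933817320945,0.968318637543394,0.967903869714523,0.967590082465671,0.967585901613644
 16.833324654726312,0.974270421896221,0.972098078720111,0.970371519144892,0.969878851131315,0.969513216786077,0.969516776065073
 17.338770965579897,0.971995048478019,0.972579048136767,0.970839865316748,0.970331783952916,0.969957059801547,0.969962608188817
 31.928603042615578,0.980959270381686,0.980410189934347,0.981698222916569,0.981438397349355,0.981323856372124,0.981406412741056
 35.767441848292947,0.981173115206871,0.982140017872704,0.983332050386888,0.983669003957547,0.983839643869548,0.983951090493522
 48.513535351958126,0.989392314859252,0.989098065534197,0.989271864167122,0.989767023048247,0.990651377245890,0.990923390420829
 48.775433388072997,0.989301126772338,0.989249512882548,0.989438718698545,0.989922840670829,0.990765843385572,0.991042041306849
 55.871203512651846,0.990306148458243,0.993178434321224,0.993305835138076,0.993426219510259,0.993627335111060,0.993888155835236
 57.217722031055018,0.993133565816627,0.993915644479165,0.993953705951051,0.994077214601124,0.994191069975879,0.994358552659916
 57.786602817941457,0.997656291239035,0.994223404591334,0.994226105870147,0.994360003032940,0.994436789470991,0.994553024874371
 59.374635195126757,0.994773899106189,0.995069025331101,0.994990982855504,0.995127500138929,0.995098141926949,0.995088597176933
 64.276473043719307,0.995700133953163,0.997382098224411,0.997371649738162,0.997228737668713,0.997155678485886,0.996551512156874
 64.886993641266599,0.999706501124434,0.997669815060163,0.997651867614479,0.997470648957411,0.997416220314930,0.996686700747082
 70.041593280620873,0.999022777053986,0.999410209696033,0.999627404499149,0.999346576305447,0.998781422048026,0.997702348250657
 80.218189861625433,1.000643266097732,1.001881745995283,1.001612224624234,1.001079688349964,1.000085000373140,0.999194855217563
 82.124036300228909,1.002648788508649,1.001667136758977,1.001254260846975,1.001077473534185,0.999805701662690,0.999387163697962
 85.646216175518930,1.003435691612409,1.001070812393098,1.000979098549795,1.000733407129447,0.999560634884124,0.999662626939243
 88.133098004618660,1.001087515609153,1.000281406655149,1.000413400680664,1.000164305672786,0.999486114859808,0.999792437555799
 89.889031456550583,0.995359451148962,0.999932188401777,0.999943240268897,0.999466702632032,0.999446237547160,0.999850934649282
 92.073539330158383,0.998640935942570,0.999352264312941,0.998961756623362,0.998813440289909,0.999394101237770,0.999884747892797
 92.199452221393585,1.001357317975222,0.999310383923151,0.998896488036070,0.998777102687298,0.999390786111064,0.999885371211662
101.381892658537254,0.998357192762669,0.995381424880887,0.995581213852261,0.997460484463660,0.998971575106642,0.999538514852964
103.805953258415684,0.994867893163075,0.994935178705211,0.995464029447219,0.997291825754917,0.998792036958702,0.999318141815402
104.114510031649843,0.996478512083150,0.994774726990739,0.995450399396903,0.997273571577789,0.998767103733914,0.999286272004187
104.500532499514520,0.990449616010681,0.994021691163945,0.995432377992272,0.997251801342518,0.998735266932354,0.999245192967004
113.003923412179574,1.000135847359190,0.998225817266761,0.997161473311423,0.997161469224959,0.997879490272719,0.998008247594698
113.217266363790259,0.998408640145447,0.998268721064115,0.997193291484002,0.997170613132397,0.997854867532202,0.997969262842715
114.350755437044427,0.997360642327377,0.998342916669927,0.997355094451975,0.997229684147825,0.997721993956831,0.997755806113633
116.834030894096941,0.998288668062457,0.998567522570403,0.997660616595265,0.997421757786681,0.997419861720732,0.997251345947084
117.134426662232727,0.996176714323217,0.998562569092955,0.997692176505418,0.997450886047899,0.997382383811845,0.997186936556043
117.501815344439819,0.997250238702309,0.998544020973495,0.997728950540761,0.997488246279979,0.997336296996208,0.997107179139263
118.333529069786891,1.001556228098799,0.998451341509376,0.997804303968175,0.997579884997398,0.997230985828050,0.996922639995505
122.278303548227996,1.000248987665619,0.997062370132470,0.997975144913602,0.998146455527194,0.996715309384767,0.995973282020139
123.611466115107760,0.993713514410905,0.996199345145869,0.997945035430834,0.998385819084392,0.996535819246323,0.995625212902158
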