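# lewisopt surrogate score table (SYNTHETIC; approximate literature
# ionization/electron-affinity and bond-dissociation energies, eV,
# quantized to 1/256 eV so floating-point sums are exact).
# ATOM <symbol> <formal charge> <score>
# BOND <symbol> <symbol> <total electrons> <score>
ATOM H 1 13.6015625
ATOM H 0 0.0
ATOM H -1 -0.75
ATOM C 4 148.0
ATOM C 3 83.5
ATOM C 2 35.6015625
ATOM C 1 11.26171875
ATOM C 0 0.0
ATOM C -1 -1.26171875
ATOM C -2 7.0
ATOM C -3 22.0
ATOM C -4 44.0
ATOM N 5 266.8984375
ATOM N 4 169.19921875
ATOM N 3 91.6015625
ATOM N 2 44.1015625
ATOM N 1 14.53125
ATOM N 0 0.0
ATOM N -1 0.0703125
ATOM N -2 7.5
ATOM N -3 21.0
ATOM O 6 433.1015625
ATOM O 5 295.0
ATOM O 4 181.3984375
ATOM O 3 103.69921875
ATOM O 2 48.69921875
ATOM O 1 13.62109375
ATOM O 0 0.0
ATOM O -1 -1.4609375
ATOM O -2 6.6015625
ATOM F 7 658.0
ATOM F 6 473.0
ATOM F 5 316.30078125
ATOM F 4 201.3984375
ATOM F 3 114.8984375
ATOM F 2 52.3984375
ATOM F 1 17.421875
ATOM F 0 0.0
ATOM F -1 -3.3984375
ATOM P 5 176.80078125
ATOM P 4 111.80078125
ATOM P 3 60.3984375
ATOM P 2 30.19921875
ATOM P 1 10.48828125
ATOM P 0 0.0
ATOM P -1 -0.75
ATOM P -2 6.0
ATOM P -3 18.0
ATOM S 6 276.5
ATOM S 5 188.19921875
ATOM S 4 115.6015625
ATOM S 3 68.3984375
ATOM S 2 33.69921875
ATOM S 1 10.359375
ATOM S 0 0.0
ATOM S -1 -2.078125
ATOM S -2 3.3984375
ATOM Cl 7 409.30078125
ATOM Cl 6 294.8984375
ATOM Cl 5 197.6015625
ATOM Cl 4 130.1015625
ATOM Cl 3 76.5
ATOM Cl 2 36.80078125
ATOM Cl 1 12.96875
ATOM Cl 0 0.0
ATOM Cl -1 -3.609375
ATOM Br 7 368.0
ATOM Br 6 265.0
ATOM Br 5 176.8984375
ATOM Br 4 117.1015625
ATOM Br 3 69.6015625
ATOM Br 2 33.6015625
ATOM Br 1 11.80859375
ATOM Br 0 0.0
ATOM Br -1 -3.359375
BOND Br Br 2 0.0
BOND Br H 2 0.0
BOND C Br 2 0.0
BOND C C 2 5.0703125
BOND C C 4 2.33984375
BOND C C 6 0.0
BOND C Cl 2 0.0
BOND C F 2 0.0
BOND C H 2 0.0
BOND C N 2 6.08984375
BOND C N 4 2.87890625
BOND C N 6 0.0
BOND C O 2 7.44921875
BOND C O 4 3.44921875
BOND C O 6 0.0
BOND C P 2 0.0
BOND C S 2 3.12890625
BOND C S 4 0.0
BOND Cl Br 2 0.0
BOND Cl Cl 2 0.0
BOND Cl H 2 0.0
BOND F Br 2 0.0
BOND F Cl 2 0.0
BOND F F 2 0.0
BOND F H 2 0.0
BOND H H 2 0.0
BOND N Br 2 0.0
BOND N Cl 2 0.0
BOND N F 2 0.0
BOND N H 2 0.0
BOND N N 2 8.109375
BOND N N 4 5.46875
BOND N N 6 0.0
BOND N O 2 4.2109375
BOND N O 4 0.0
BOND N P 2 0.0
BOND N S 2 2.0
BOND N S 4 0.0
BOND O Br 2 0.0
BOND O Cl 2 0.0
BOND O F 2 0.0
BOND O H 2 0.0
BOND O O 2 3.640625
BOND O O 4 0.0
BOND O P 2 2.69921875
BOND O P 4 0.0
BOND O S 2 1.609375
BOND O S 4 0.0
BOND P Br 2 0.0
BOND P Cl 2 0.0
BOND P F 2 0.0
BOND P H 2 0.0
BOND P P 2 0.0
BOND S Br 2 0.0
BOND S Cl 2 0.0
BOND S F 2 0.0
BOND S H 2 0.0
BOND S P 2 0.0
BOND S S 2 2.0703125
BOND S S 4 0.0
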