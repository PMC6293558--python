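H BLAM930101
D Alpha helix propensity of position 44 in T4 lysozyme (values rescaled by the index maximum)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  1.000000  0.802083  0.406250  0.437500  0.437500  0.833333  0.552083  0.000000  0.593750  0.875000
  0.958333  0.760417  0.895833  0.614583 -2.604167  0.552083  0.562500  0.604167  0.750000  0.656250
//
H BIOV880101
D Information value for accessibility; average fraction 35% (values rescaled by the index maximum)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  0.084656 -0.370370 -0.391534 -0.412698  0.888889 -0.386243 -0.560847 -0.068783  0.264550  0.798942
  0.767196 -0.746032  0.656085  1.000000 -0.105820 -0.370370 -0.201058  0.767196  0.280423  0.650794
//
H MAXF760101
D Normalized frequency of alpha-helix (values rescaled by the index maximum)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  0.856287  0.706587  0.383234  0.550898  0.562874  0.730539  1.000000  0.275449  0.586826  0.622754
  0.814371  0.760479  0.916168  0.712575  0.293413  0.419162  0.467066  0.604790  0.413174  0.586826
//
H TSAJ990101
D Volumes including the crystallographic waters using the ProtOr (values rescaled by the index maximum)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  0.394435  0.840548  0.540636  0.505300  0.452739  0.648852  0.613074  0.281802  0.695671  0.719965
  0.720406  0.729240  0.732332  0.842756  0.537102  0.416078  0.528269  1.000000  0.859541  0.610424
//
H NAKH920108
D AA composition of MEM of multi-spanning proteins (values reconstructed on the max-normalized scale from the reference deviation profile)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  0.562000  0.016000  0.138000  0.056000  0.153000  0.068000  0.056000  0.370000  0.028000  0.825000
  1.000000  0.034000  0.236000  0.660000  0.117000  0.335000  0.281000  0.132000  0.188000  0.745000
//
H CEDJ970104
D Composition of amino acids in intracellular proteins (percent) (values reconstructed on the max-normalized scale from the reference deviation profile)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  0.918000  0.569000  0.465000  0.639000  0.221000  0.651000  0.825000  0.825000  0.244000  0.604000
  1.000000  0.779000  0.279000  0.453000  0.546000  0.767000  0.546000  0.139000  0.360000  0.790000
//
H LIFS790101
D Conformational preference for total beta-strand (values rescaled by the index maximum)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  0.508287  0.513812  0.331492  0.265193  0.640884  0.524862  0.337017  0.337017  0.513812  1.000000
  0.718232  0.386740  0.657459  0.690608  0.220994  0.453039  0.618785  0.850829  0.845304  0.994475
//
H MIYS990104
D Optimized relative partition energies - method C (values reconstructed on the max-normalized scale from the reference deviation profile)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
 -0.121000  0.212000  0.394000  0.576000 -1.152000  0.424000  0.697000  0.273000 -0.121000 -1.030000
 -1.121000  1.000000 -0.909000 -1.152000  0.576000  0.364000  0.091000 -1.000000 -0.879000 -0.879000
//
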