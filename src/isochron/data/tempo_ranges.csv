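musical_name,rank,reference_hz,from_hz,to_hz,reference_ms,from_ms,to_ms
Adagio,1,1.067,1.017,1.133,937.21,983.28,882.61
Andante,2,1.333,1.283,1.400,750.19,779.42,714.29
,3,1.600,1.550,1.667,625.00,645.16,599.88
Moderato,4,1.867,1.817,1.933,535.62,550.36,517.33
,5,2.133,2.083,2.200,468.82,480.08,454.55
Allegro,6,2.400,2.350,2.467,416.67,425.53,405.35
,7,2.700,2.617,2.800,370.37,382.12,357.14
Presto,8,2.933,2.817,3.000,340.95,354.99,333.33
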