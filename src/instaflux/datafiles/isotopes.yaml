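# Natural isotope abundances as (mass shift, fraction) pairs per element.
# Standard terrestrial values; configurable for tracer purity corrections.
C: [[0, 0.9893], [1, 0.0107]]
H: [[0, 0.999885], [1, 0.000115]]
N: [[0, 0.99636], [1, 0.00364]]
O: [[0, 0.99757], [1, 0.00038], [2, 0.00205]]
S: [[0, 0.9499], [1, 0.0075], [2, 0.0425]]
P: [[0, 1.0]]
Si: [[0, 0.92223], [1, 0.04685], [2, 0.03092]]
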