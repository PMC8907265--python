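# Background amino-acid frequencies estimated from large non-redundant
# protein databases, as conventionally used to weight positional
# conservation in coupling analyses. Order: A C D E F G H I K L M N P Q R S T V W Y
0.073 0.025 0.050 0.061 0.042 0.072 0.023 0.053 0.064 0.089 0.023 0.043 0.052 0.040 0.052 0.073 0.056 0.063 0.013 0.033
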