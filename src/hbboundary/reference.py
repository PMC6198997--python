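"""Published experimental reference values for comparison plots.

These numbers come from MS2-MCP live-imaging analyses of *hunchback*
transcription in nuclear cycles 12-13 and are shipped only as
reference constants to draw alongside model predictions; nothing in
the package's own computations depends on them.
"""

#: Fitted Hill coefficient of the mRNA expression boundary.
H_DATA = {"nc12": 6.9, "nc13": 7.1}
#: 95% confidence intervals of the fitted Hill coefficient.
H_DATA_CI = {"nc12": (5.80, 8.64), "nc13": (6.20, 8.32)}

#: Experimental positional resolution, % egg length.
DELTA_X_DATA_EL = {"nc12": 14.0, "nc13": 12.0}
DELTA_X_DATA_CI_EL = {"nc12": (11.0, 20.0), "nc13": (8.0, 18.0)}

#: Readout error of total mRNA per nucleus in the boundary strip.
MRNA_CV_DATA = {"nc12": 0.82, "nc13": 0.69}

#: Strip CVs of the nc13 embryos aligned at half-max: the strip at the
#: boundary (-5% EL) versus mid-embryo (0% EL).
STRIP_CV_NC13 = {"-5% EL": 0.69, "0% EL": 1.78}
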