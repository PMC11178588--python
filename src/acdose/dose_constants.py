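"""Unit-conversion constants used by the dosimetry module."""

#: joules per MeV
J_PER_MEV = 1.602e-13
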