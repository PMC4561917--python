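"""Physical constants in the package's working units (eV, fs, K)."""

#: Reduced Planck constant, eV * fs.
HBAR_EV_FS = 0.6582119569

#: Boltzmann constant, eV / K.
KB_EV_K = 8.617333262e-5

#: Wavenumber-to-energy conversion, eV per cm^-1.
EV_PER_CM1 = 1.239841984e-4

#: Gaussian FWHM / sigma.
FWHM_PER_SIGMA = 2.3548200450309493
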