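"""Published calibration constants used as generator inputs.

These are the literature values the surrogate pipeline is calibrated
against: the sequential-model rate constants of the two internal-conversion
steps, the measured pump-probe lifetimes, and the calculated Soret-Qy peak
gaps.  They parameterise synthetic-data generators and round-trip checks;
nothing in the package asserts them as outputs.
"""

from __future__ import annotations

#: Sequential-model rate constants, fs^-1: B->Qx (k1) and Qx->Qy (k2).
SEQUENTIAL_RATES_PER_FS = {
    "chla": {"k1": 0.0101, "k2": 0.00781},
    "chlb": {"k1": 0.0173, "k2": 0.00481},
}

#: Measured Sn -> S1 internal-conversion lifetimes from pump-probe global
#: analysis, fs.
TA_LIFETIMES_FS = {"chla": 143.0, "chlb": 162.0}

#: Calculated Soret-peak minus Qy-peak gaps of the ensemble spectra, eV.
SORET_QY_GAP_EV = {"chla": 1.24, "chlb": 1.12}

#: Batch size of the trajectory-count convergence analysis.
CONVERGENCE_BATCH_SIZE = 100
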