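"""Shared defaults for the CSP analysis.

Concentrations are millimolar everywhere inside the package; dissociation
constants are converted to micromolar only at reporting interfaces.
"""

ALPHA_N = 0.154
"""^15N scaling factor for the combined amide shift metric.

Weights nitrogen shift differences so they are commensurate with proton
differences; the value is the BMRB-derived ratio of average shift variances
conventionally used for backbone amides.
"""

MAX_STEP_PPM = 0.05
"""Largest allowed point-to-point peak movement (scaled ppm) during tracking."""

OVERLAP_TOL_PPM = 0.01
"""Scaled-ppm radius below which two peaks are considered overlapped."""

TRANSFER_TOL_PPM = 0.02
"""Scaled-ppm radius for assignment transfer between related spectra."""

TIE_TOL_PPM = 1e-9
"""Distances closer than this are exact ties; tied matches are rejected."""

NOISE_SIGMA_PPM = 0.003
"""Default peak-position noise SD (scaled ppm) of the synthetic generator."""

PROTEIN_TOTAL_MM = 0.4
"""Default total protein concentration (mM) of a titration."""
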