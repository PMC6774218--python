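"""Default cohort parameter sets: published group means ± SD.

These dictionaries hold the per-genotype, per-age population values the
synthetic cohort generator uses as ground truth: dark-adapted ERG
amplitudes (a-wave, b-wave, pSTR, total oscillatory potential, all μV)
and OCT-derived inner/outer retinal thickness (μm) for APP/PS1 mice and
wild-type littermates followed at 3, 6, 9 and 12 months of age.  The
"sd" entries are between-animal (cohort) standard deviations.

The a-wave means are stored as printed, i.e. signed negative; the
generator uses the magnitude for waveform construction and the summary
step reports the signed value.
"""

from __future__ import annotations

GENOTYPES = ("APP/PS1", "WT")
AGES_MONTHS = (3, 6, 9, 12)
NOR_AGES_MONTHS = (6, 9, 12)

#: Functional (ERG) group means ± SD in μV per (genotype, age in months).
ERG_MEANS: dict[tuple[str, int], dict[str, float]] = {
    ("APP/PS1", 3): {"a": -157.6, "a_sd": 38, "b": 217.5, "b_sd": 40,
                     "pstr": 123.0, "pstr_sd": 22, "op": 173.5, "op_sd": 29},
    ("APP/PS1", 6): {"a": -136.7, "a_sd": 28, "b": 174.7, "b_sd": 35,
                     "pstr": 77.1, "pstr_sd": 15, "op": 119.3, "op_sd": 29},
    ("APP/PS1", 9): {"a": -118.9, "a_sd": 38, "b": 146.2, "b_sd": 43,
                     "pstr": 66.5, "pstr_sd": 8, "op": 92.9, "op_sd": 30},
    ("APP/PS1", 12): {"a": -116.0, "a_sd": 57, "b": 107.7, "b_sd": 37,
                      "pstr": 49.8, "pstr_sd": 12, "op": 98.6, "op_sd": 24},
    ("WT", 3): {"a": -144.5, "a_sd": 45, "b": 174.6, "b_sd": 31,
                "pstr": 112.9, "pstr_sd": 9, "op": 117.1, "op_sd": 29},
    ("WT", 6): {"a": -144.3, "a_sd": 30, "b": 155.0, "b_sd": 21,
                "pstr": 99.4, "pstr_sd": 18, "op": 109.1, "op_sd": 23},
    ("WT", 9): {"a": -135.4, "a_sd": 29, "b": 137.6, "b_sd": 34,
                "pstr": 83.4, "pstr_sd": 16, "op": 80.7, "op_sd": 24},
    ("WT", 12): {"a": -123.2, "a_sd": 33, "b": 118.0, "b_sd": 31,
                 "pstr": 74.8, "pstr_sd": 11, "op": 68.5, "op_sd": 18},
}

#: Structural (OCT) group means ± SD in μm per (genotype, age in months).
THICKNESS_MEANS: dict[tuple[str, int], dict[str, float]] = {
    ("APP/PS1", 3): {"inner": 31.2, "inner_sd": 0.8, "outer": 54.7, "outer_sd": 1.4},
    ("APP/PS1", 6): {"inner": 30.0, "inner_sd": 1.1, "outer": 53.0, "outer_sd": 1.9},
    ("APP/PS1", 9): {"inner": 29.0, "inner_sd": 1.0, "outer": 52.1, "outer_sd": 2.0},
    ("APP/PS1", 12): {"inner": 28.5, "inner_sd": 0.7, "outer": 51.0, "outer_sd": 2.3},
    ("WT", 3): {"inner": 31.3, "inner_sd": 0.7, "outer": 54.1, "outer_sd": 1.0},
    ("WT", 6): {"inner": 30.5, "inner_sd": 0.9, "outer": 53.9, "outer_sd": 1.7},
    ("WT", 9): {"inner": 30.4, "inner_sd": 0.7, "outer": 53.5, "outer_sd": 1.5},
    ("WT", 12): {"inner": 30.1, "inner_sd": 0.9, "outer": 53.1, "outer_sd": 1.0},
}

# Novel-object-recognition exploration-time means (s).  The source study
# reports the discrimination index only graphically (non-significant drift
# in both groups from 6 to 12 months), so these package defaults encode a
# ~20 s total exploration budget with a mild opposite drift of the index
# (APP/PS1 declining, WT rising), matching the reported qualitative trend.
NOR_MEANS: dict[tuple[str, int], dict[str, float]] = {
    ("APP/PS1", 6): {"novel": 13.0, "familiar": 7.0, "sd": 3.0},
    ("APP/PS1", 9): {"novel": 12.7, "familiar": 7.3, "sd": 3.0},
    ("APP/PS1", 12): {"novel": 12.4, "familiar": 7.6, "sd": 3.0},
    ("WT", 6): {"novel": 12.8, "familiar": 7.2, "sd": 3.0},
    ("WT", 9): {"novel": 13.1, "familiar": 6.9, "sd": 3.0},
    ("WT", 12): {"novel": 13.3, "familiar": 6.7, "sd": 3.0},
}
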