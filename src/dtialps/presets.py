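"""Calibrated group presets for the three-group T2DM cohort.

The cohort emulates a case–control study of the glymphatic system in type 2
diabetes: healthy controls (HC), T2DM with normal cognition (DMNC), and
T2DM with mild cognitive impairment (DMMCI). Per-hemisphere ALPS targets
(mean, SD) and the covariate distributions follow the study population the
generator is calibrated to; ALPS means are imposed exactly through the
numerator diffusivities and the printed SD through a moment-matched
lognormal subject factor (sigma² = ln(1 + CV²)) — see ``GroupPreset``.

Covariate tuples: ("normal", mean, sd), ("normal_iqr", median, q1, q3),
("lognormal_iqr", median, q1, q3), ("bernoulli", p_male), ("missing",).
"""

from __future__ import annotations

from dtialps.phantom import GroupPreset

GROUP_SIZES = {"HC": 37, "DMNC": 37, "DMMCI": 39}

#: Per-group ALPS population targets: {side: (mean, sd)}.
ALPS_TARGETS = {
    "HC": {"left": (1.76, 0.26), "right": (1.59, 0.21)},
    "DMNC": {"left": (1.80, 0.25), "right": (1.58, 0.22)},
    "DMMCI": {"left": (1.68, 0.23), "right": (1.48, 0.19)},
}

_COVARIATES = {
    "HC": {
        "gender": ("bernoulli", 11 / 37),
        "age": ("normal_iqr", 51, 45, 59),
        "education": ("normal_iqr", 10, 8, 15),
        "duration": ("missing",),
        "bmi": ("normal_iqr", 22.94, 21.3, 24.12),
        "sbp": ("normal", 124.22, 12.96),
        "dbp": ("normal", 82.59, 8.95),
        "hba1c": ("lognormal_iqr", 5.7, 5.5, 5.9),
        "fpg": ("lognormal_iqr", 5.14, 4.8, 5.51),
        "fins": ("lognormal_iqr", 7.65, 5.74, 10.4),
        "homa_ir": ("lognormal_iqr", 1.72, 1.41, 2.36),
        "ldl": ("normal_iqr", 3.05, 2.72, 3.31),
        "hdl": ("normal_iqr", 1.47, 1.2, 1.84),
        "tg": ("lognormal_iqr", 1.28, 0.89, 1.58),
        "tc": ("normal_iqr", 4.92, 4.6, 5.58),
        "moca": ("normal_iqr", 28, 27, 28.5),
        "avlt_immediate": ("normal", 22.78, 4.45),
        "avlt_5min": ("normal", 8.62, 1.53),
        "avlt_delay": ("normal_iqr", 9, 8, 10),
        "avlt_recall": ("normal_iqr", 12, 11, 12.5),
        "gpt_r": ("lognormal_iqr", 62, 55, 69),
        "gpt_l": ("lognormal_iqr", 67, 60, 75),
        "dst_forward": ("normal_iqr", 8, 7, 9),
        "dst_backward": ("normal_iqr", 4, 3, 5),
        "cdt": ("normal_iqr", 4, 3, 4.5),
        "dsst": ("normal_iqr", 45, 36, 54),
        "tmt_a": ("lognormal_iqr", 42, 31, 54),
    },
    "DMNC": {
        "gender": ("bernoulli", 15 / 37),
        "age": ("normal_iqr", 49, 45, 55),
        "education": ("normal_iqr", 12, 9, 15),
        "duration": ("lognormal_iqr", 4, 2, 12),
        "bmi": ("normal_iqr", 23.73, 22.04, 25.62),
        "sbp": ("normal", 120.38, 14.08),
        "dbp": ("normal", 81.81, 9.13),
        "hba1c": ("lognormal_iqr", 7.7, 6.5, 9.1),
        "fpg": ("lognormal_iqr", 6.73, 3.74, 10.79),
        "fins": ("lognormal_iqr", 7.7, 6.5, 9.1),
        "homa_ir": ("lognormal_iqr", 2.28, 1.39, 3.78),
        "ldl": ("normal_iqr", 3.39, 2.92, 3.79),
        "hdl": ("normal_iqr", 1.12, 0.99, 1.43),
        "tg": ("lognormal_iqr", 1.41, 1.03, 2.35),
        "tc": ("normal_iqr", 5.12, 4.55, 5.41),
        "moca": ("normal_iqr", 27, 26.5, 28),
        "avlt_immediate": ("normal", 21.68, 4.36),
        "avlt_5min": ("normal", 8.32, 1.8),
        "avlt_delay": ("normal_iqr", 8, 7, 9),
        "avlt_recall": ("normal_iqr", 12, 11, 12.5),
        "gpt_r": ("lognormal_iqr", 72, 64, 88),
        "gpt_l": ("lognormal_iqr", 77, 69, 89),
        "dst_forward": ("normal_iqr", 8, 6, 9),
        "dst_backward": ("normal_iqr", 5, 4, 5.5),
        "cdt": ("normal_iqr", 4, 3.5, 4.5),
        "dsst": ("normal_iqr", 39, 30, 50),
        "tmt_a": ("lognormal_iqr", 43, 37, 47),
    },
    "DMMCI": {
        "gender": ("bernoulli", 19 / 39),
        "age": ("normal_iqr", 53, 48.5, 59),
        "education": ("normal_iqr", 9, 8, 12),
        "duration": ("lognormal_iqr", 4, 2, 8.5),
        "bmi": ("normal_iqr", 23.39, 20.79, 26.01),
        "sbp": ("normal", 127.26, 15.75),
        "dbp": ("normal", 82.1, 8.74),
        "hba1c": ("lognormal_iqr", 7.4, 6.4, 9.15),
        "fpg": ("lognormal_iqr", 6.6, 6.0, 7.84),
        "fins": ("lognormal_iqr", 6.94, 4.745, 12.03),
        "homa_ir": ("lognormal_iqr", 2.21, 1.45, 4.41),
        "ldl": ("normal_iqr", 2.9, 2.285, 3.4),
        "hdl": ("normal_iqr", 1.14, 0.94, 1.45),
        "tg": ("lognormal_iqr", 1.45, 1.095, 2.14),
        "tc": ("normal_iqr", 4.74, 3.745, 5.42),
        "moca": ("normal_iqr", 23, 21, 25),
        "avlt_immediate": ("normal", 18.97, 4.11),
        "avlt_5min": ("normal", 6.56, 2.07),
        "avlt_delay": ("normal_iqr", 6, 5, 7.5),
        "avlt_recall": ("normal_iqr", 11, 10, 12),
        "gpt_r": ("lognormal_iqr", 83, 69, 98.5),
        "gpt_l": ("lognormal_iqr", 87, 78, 113),
        "dst_forward": ("normal_iqr", 8, 6, 8.5),
        "dst_backward": ("normal_iqr", 4, 3, 5),
        "cdt": ("normal_iqr", 4, 3, 4.5),
        "dsst": ("normal_iqr", 32, 26.5, 41.5),
        "tmt_a": ("lognormal_iqr", 48, 41.5, 68),
    },
}

# Hippocampal microstructure does not separate the groups (whole-label
# averaging washes out subfield effects), but in the diabetic groups RD is
# negatively coupled to the subject's ALPS level, reproducing the
# ALPS–microstructure association seen only under disease.
_HIPPO_COUPLING = {"HC": 0.0, "DMNC": 0.45, "DMMCI": 0.45}
_AVLT_COUPLING = {"HC": 0.2, "DMNC": 0.2, "DMMCI": 0.2}


def make_preset(group: str) -> GroupPreset:
    targets = ALPS_TARGETS[group]
    return GroupPreset(
        name=group,
        alps_mean={s: targets[s][0] for s in ("left", "right")},
        alps_sd={s: targets[s][1] for s in ("left", "right")},
        alps_rd_coupling=_HIPPO_COUPLING[group],
        alps_avlt_coupling=_AVLT_COUPLING[group],
        covariates=dict(_COVARIATES[group]),
    )


def default_presets() -> tuple[GroupPreset, GroupPreset, GroupPreset]:
    """The calibrated (HC, DMNC, DMMCI) presets."""
    return tuple(make_preset(g) for g in ("HC", "DMNC", "DMMCI"))
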