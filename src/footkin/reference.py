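"""Published group summary statistics used as worked-example inputs.

``GROUP_MEANS`` holds the reported group means (N = 18 university-level
dancers) for the kinematic variables across the four study conditions:
natural double-leg upright posture, functional turnout, forced turnout,
and sautes in first position.  Units are degrees, except navicular drop
(mm).  Navicular drop has no natural-stance cell: it is zero there by
definition (the natural posture is the reference height).

``GROUP_SE`` holds the corresponding standard errors.  These tables are
inputs for the delta/classification utilities and for configuring
realistic synthetic cohorts; nothing in the pipeline fits to them.
"""

from __future__ import annotations

__all__ = ["GROUP_MEANS", "GROUP_SE", "N_SUBJECTS"]

N_SUBJECTS = 18

GROUP_MEANS: dict[str, dict[str, float]] = {
    "hindfoot_eversion": {
        "natural": 1.1,
        "functional": 5.7,
        "forced": 7.1,
        "saute": 15.8,
    },
    "midfoot_abduction": {
        "natural": 2.8,
        "functional": 5.6,
        "forced": 6.3,
        "saute": 7.7,
    },
    "forefoot_abduction": {
        "natural": 7.6,
        "functional": 8.4,
        "forced": 8.8,
        "saute": 8.7,
    },
    "navicular_drop_mm": {
        "functional": 1.6,
        "forced": 1.9,
        "saute": 12.9,
    },
    "mtpj_abduction": {
        "natural": 10.7,
        "functional": 12.0,
        "forced": 13.5,
        "saute": 13.1,
    },
}

GROUP_SE: dict[str, dict[str, float]] = {
    "hindfoot_eversion": {
        "natural": 0.8,
        "functional": 0.9,
        "forced": 0.9,
        "saute": 1.6,
    },
    "midfoot_abduction": {
        "natural": 1.2,
        "functional": 1.3,
        "forced": 1.3,
        "saute": 1.3,
    },
    "forefoot_abduction": {
        "natural": 1.0,
        "functional": 1.0,
        "forced": 1.0,
        "saute": 1.1,
    },
    "navicular_drop_mm": {
        "functional": 0.9,
        "forced": 1.0,
        "saute": 1.2,
    },
    "mtpj_abduction": {
        "natural": 1.6,
        "functional": 1.6,
        "forced": 1.8,
        "saute": 1.8,
    },
}
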