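"""Published cross-tabulations from the motivating survey (n = 517).

Counts of participant characteristics by academic-performance profile
(rows: low self-regulators n=475, high self-regulators n=42) as printed
in the survey report of 517 Chinese undergraduates. These are inputs,
not outputs: the package recomputes the profile-difference statistics
and the sparse-cell screen from them.

The ``english_proficiency`` rows were printed with the two profile
columns swapped in the source table; the counts are stored as printed —
the sparse-cell screen depends only on the cell values, not on which
profile they belong to.
"""

from __future__ import annotations

import numpy as np

N_TOTAL = 517
N_COLLECTED = 548
N_HIGH = 42
N_LOW = 475

#: profile-by-level counts, rows (low, high), one entry per categorical variable
CATEGORICAL_COUNTS: dict[str, np.ndarray] = {
    "gender": np.array([[207, 268], [19, 23]]),  # male, female
    "ethnic": np.array([[468, 7], [42, 0]]),  # han, minority
    "political_belief": np.array([[34, 261, 180], [13, 25, 4]]),
    "academic_year": np.array([[36, 213, 209, 17], [1, 18, 21, 2]]),
    "high_school_track": np.array([[176, 281, 18], [15, 26, 1]]),
    "gaokao_attempts": np.array([[384, 86, 5], [34, 8, 0]]),
    "scholarship": np.array([[77, 398], [11, 31]]),  # yes, no
    "english_proficiency": np.array([[18, 5, 19], [171, 40, 264]]),  # as printed (columns swapped in source)
    "leadership_experience": np.array([[290, 185], [30, 12]]),
    "current_leadership": np.array([[175, 300], [20, 22]]),
    "major_change": np.array([[97, 378], [6, 36]]),
    "military_service": np.array([[4, 471], [1, 41]]),
    "volunteer": np.array([[362, 113], [39, 3]]),
    "father_education": np.array([[58, 227, 190], [3, 16, 23]]),
    "mother_education": np.array([[95, 213, 167], [3, 17, 22]]),
}

#: ordinal / continuous characteristics, always multivariate candidates
CONTINUOUS_VARS = ["exercise_freq", "late_bedtime_freq", "fas", "psss", "gses"]

#: Yates-corrected 2x2 chi-squares as printed in the survey report
PRINTED_CHI2_2X2 = {
    "gender": 0.00,
    "scholarship": 2.06,
    "leadership_experience": 1.35,
    "current_leadership": 1.48,
    "major_change": 0.57,
    "volunteer": 5.23,
}

#: 3x2 uncorrected chi-square printed for mother's educational attainment
PRINTED_CHI2_MOTHER = 6.66

#: multivariate candidate set after the sparse-cell (<10) screen
CANDIDATE_SET = [
    "gender",
    "scholarship",
    "leadership_experience",
    "current_leadership",
    "exercise_freq",
    "late_bedtime_freq",
    "fas",
    "psss",
    "gses",
]
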