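"""Packaged chronic post-stroke aphasia cohort: demographics, behaviour, and
reference factor solutions.

The package ships the published 31-patient cohort as plain TSV fixtures: one
demographics table (age, gender, education, months post-stroke, lesion volume
in voxels, clinical aphasia label), one 31 x 21 behavioural score matrix
(percent scores on a neuropsychological battery plus four connected-speech
measures: WPM, TTR, MLU and token count), and the reference rotated-PCA
loadings and per-patient factor scores for the speech-only and omnibus
solutions.  Loaders validate shape and ranges and fail naming the offending
row/column.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

N_PATIENTS = 31
N_MEASURES = 21

#: the four connected-speech measures, in score-matrix column order
SPEECH_MEASURES = ["wpm", "ttr", "mlu", "tokens"]


@dataclass(frozen=True)
class PatientRecord:
    """Demographic and lesion summary for one patient."""

    patient_id: str
    age: int
    gender: str
    education_years: int
    months_post_stroke: int
    lesion_volume: int
    aphasia_label: str

    def __post_init__(self):
        if self.lesion_volume <= 0:
            raise ValueError(f"{self.patient_id}: lesion_volume must be positive")
        if self.months_post_stroke < 12:
            raise ValueError(
                f"{self.patient_id}: cohort inclusion requires >= 12 months post-stroke"
            )
        if self.gender not in ("M", "F"):
            raise ValueError(f"{self.patient_id}: gender must be M or F")


@dataclass(frozen=True)
class ReferenceFactors:
    """Published reference factor solutions.

    ``speech_loadings``: 4 measures x 2 factors (speech-only solution);
    ``omnibus_loadings``: 21 measures x 4 factors;
    ``factor_scores``: per-patient scores — three columns from the earlier
    battery-only decomposition (phonology, semantics, executive), two from the
    speech-only solution (F1 speech quanta, F2 semantic variety) and four
    omnibus columns.
    """

    speech_loadings: pd.DataFrame
    omnibus_loadings: pd.DataFrame
    factor_scores: pd.DataFrame


def _data_path(name: str):
    return resources.files("pcavbcm.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", index_col=0)


def load_cohort() -> tuple[list[PatientRecord], pd.DataFrame]:
    """Load the packaged cohort.

    Returns the 31 patient records and the 31 x 21 percent-score matrix
    (rows: patients, columns: measures in the packaged column order, the four
    speech measures last).
    """
    demo = _read_tsv("cohort_demographics.tsv")
    scores = _read_tsv("behaviour_scores.tsv")
    if len(demo) != N_PATIENTS:
        raise ValueError(f"expected {N_PATIENTS} patients, found {len(demo)}")
    if scores.shape != (N_PATIENTS, N_MEASURES):
        raise ValueError(
            f"expected {N_PATIENTS}x{N_MEASURES} score matrix, got {scores.shape}"
        )
    if list(scores.index) != list(demo.index):
        raise ValueError("score-matrix rows do not match demographics rows")
    if scores.isna().any().any():
        col = scores.columns[scores.isna().any().to_numpy()][0]
        row = scores.index[scores[col].isna()][0]
        raise ValueError(f"missing score at patient {row}, measure {col}")
    vals = scores.to_numpy(float)
    if (vals < 0).any() or (vals > 100).any():
        i, j = np.argwhere((vals < 0) | (vals > 100))[0]
        raise ValueError(
            f"score out of [0, 100] at patient {scores.index[i]}, "
            f"measure {scores.columns[j]}"
        )
    records = [
        PatientRecord(
            patient_id=str(pid),
            age=int(row.age),
            gender=str(row.gender),
            education_years=int(row.education_years),
            months_post_stroke=int(row.months_post_stroke),
            lesion_volume=int(row.lesion_volume),
            aphasia_label=str(row.aphasia_label),
        )
        for pid, row in demo.iterrows()
    ]
    return records, scores


def lesion_volumes() -> pd.Series:
    """Per-patient lesion volume (voxel counts) from the demographics table."""
    demo = _read_tsv("cohort_demographics.tsv")
    return demo["lesion_volume"].astype(int)


def load_reference_factors() -> ReferenceFactors:
    """Load the published loadings and factor-score tables."""
    speech = _read_tsv("reference_speech_loadings.tsv")
    omni = _read_tsv("reference_omnibus_loadings.tsv")
    scores = _read_tsv("reference_factor_scores.tsv")
    for name, tbl in (("speech", speech), ("omnibus", omni)):
        arr = tbl.to_numpy(float)
        if (np.abs(arr) > 1).any():
            i, j = np.argwhere(np.abs(arr) > 1)[0]
            raise ValueError(
                f"{name} loading out of [-1, 1] at {tbl.index[i]}, {tbl.columns[j]}"
            )
    if len(scores) != N_PATIENTS:
        raise ValueError(f"expected {N_PATIENTS} factor-score rows, got {len(scores)}")
    # printed to 3 dp, so column means are only approximately zero
    if (scores.mean().abs() > 0.05).any():
        bad = scores.mean().abs().idxmax()
        raise ValueError(f"factor-score column {bad} is not centred")
    return ReferenceFactors(speech, omni, scores)
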