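"""Bundled worked-example data.

``cohort_readings`` is a published per-patient classification table
for a 20-patient independent test cohort of contrast-enhancing brain
tumors: the histological diagnosis and the predicted entity from three
machine-learning models (AdaBoost on advMRI features, random forest on
phyMRI features, AdaBoost on combined cMRI + phyMRI features) and from
consensus human reading.  It serves as a small end-to-end example for the
error-counting and evaluation utilities; the counting here recomputes the
error totals from the per-patient entries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cohort_readings", "classification_errors",
           "reading_confusion"]

_ROWS = [
    # id, histology, ada_advmri, rf_phymri, ada_cmri_phymri, human
    (1, "META", "META", "META", "META", "META"),
    (2, "MNG", "MNG", "MNG", "MNG", "MNG"),
    (3, "GBM", "GBM", "META", "GBM", "GBM"),
    (4, "GBM", "GBM", "GBM", "GBM", "GBM"),
    (5, "GBM", "GBM", "GBM", "GBM", "PCNSL"),
    (6, "MNG", "MNG", "MNG", "MNG", "MNG"),
    (7, "META", "GBM", "GBM", "META", "AG"),
    (8, "META", "GBM", "GBM", "GBM", "META"),
    (9, "GBM", "GBM", "GBM", "GBM", "GBM"),
    (10, "GBM", "GBM", "GBM", "GBM", "GBM"),
    (11, "GBM", "GBM", "GBM", "GBM", "AG"),
    (12, "GBM", "GBM", "META", "META", "META"),
    (13, "AG", "AG", "AG", "AG", "AG"),
    (14, "GBM", "GBM", "GBM", "GBM", "GBM"),
    (15, "AG", "AG", "AG", "AG", "PCNSL"),
    (16, "AG", "AG", "AG", "AG", "AG"),
    (17, "META", "GBM", "META", "PCNSL", "GBM"),
    (18, "META", "PCNSL", "META", "PCNSL", "META"),
    (19, "GBM", "GBM", "GBM", "GBM", "GBM"),
    (20, "MNG", "GBM", "GBM", "GBM", "MNG"),
]

READER_COLUMNS = ("ada_advmri", "rf_phymri", "ada_cmri_phymri", "human")


def cohort_readings() -> pd.DataFrame:
    """The 20-patient reference table (histology + four readings)."""
    return pd.DataFrame(
        _ROWS,
        columns=["patient", "histology", *READER_COLUMNS],
    ).set_index("patient")


def classification_errors(reading: str) -> int:
    """Number of misclassified patients for one reading column."""
    df = cohort_readings()
    if reading not in READER_COLUMNS:
        raise ValueError(f"unknown reading {reading!r}; "
                         f"choose from {READER_COLUMNS}")
    return int((df[reading] != df["histology"]).sum())


def reading_confusion(reading: str) -> pd.DataFrame:
    """Confusion matrix (histology × prediction) for one reading column."""
    df = cohort_readings()
    classes = sorted(set(df["histology"]) | set(df[reading]))
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(df["histology"], df[reading]):
        cm[classes.index(t), classes.index(p)] += 1
    return pd.DataFrame(cm, index=classes, columns=classes)
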