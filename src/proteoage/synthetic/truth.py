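"""Ground-truth sidecar for synthetic datasets."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MECHANISM_CLASSES = (
    "concordant-significant",
    "transcript-consistent",
    "no-transcript",
    "miRNA-candidate",
    "other-post-transcriptional",
    "null",
)


@dataclass
class SyntheticTruth:
    """Everything a generator injected, in recoverable form.

    Only the fields relevant to the generating module are populated; the
    rest stay ``None``. Serializes to a JSON sidecar.
    """

    seed: int | None = None
    # cohort
    mechanism_class: pd.Series | None = None  # gene -> class
    protein_shift: pd.DataFrame | None = None  # gene x group, log2
    transcript_shift: pd.DataFrame | None = None  # gene x group, log2
    target_correlations: dict | None = None  # group -> target r
    solved_noise: dict | None = None  # group -> per-sample protein noise sd (log10)
    mirna_targets: dict | None = None  # miRNA -> [genes]
    # psm
    protein_abundances: pd.DataFrame | None = None
    zero_peptide_proteins: list | None = None
    low_score_fraction: float | None = None
    # sec
    complex_apex: dict | None = None  # complex -> young apex fraction
    sec_shifts: dict | None = None  # complex -> injected old-condition offset
    # stoichiometry
    perturbed_complexes: dict | None = None  # complex -> {member: log2 shift}
    # aggregates
    enriched_proteins: dict | None = None  # protein -> injected log2 shift
    score_link: str | None = None
    # survival
    cox_coefficients: pd.Series | None = None  # gene -> c_i
    baseline_rate: float | None = None
    risk_sets: dict | None = None

    def to_json(self, path) -> None:
        payload = {}
        for key, value in self.__dict__.items():
            if value is None:
                continue
            if isinstance(value, pd.Series):
                payload[key] = {"__series__": value.to_dict()}
            elif isinstance(value, pd.DataFrame):
                payload[key] = {"__frame__": value.to_dict(orient="index")}
            elif isinstance(value, (np.floating, np.integer)):
                payload[key] = value.item()
            else:
                payload[key] = value
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {}
        for key, value in payload.items():
            if isinstance(value, dict) and "__series__" in value:
                kwargs[key] = pd.Series(value["__series__"])
            elif isinstance(value, dict) and "__frame__" in value:
                kwargs[key] = pd.DataFrame.from_dict(value["__frame__"], orient="index")
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
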