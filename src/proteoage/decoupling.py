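"""Transcript-protein decoupling analysis.

Three readouts: per-sample global correlation between matched protein and
transcript abundances (with a one-way ANOVA across age groups);
fold-change concordance quadrants over jointly significant features; and
the five-class regulatory-mechanism classification of age-affected
proteins (concordant, transcript-consistent, transcript-not-detected,
miRNA-candidate, other post-transcriptional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix

log = logging.getLogger(__name__)

MECHANISM_ORDER = (
    "concordant-significant",
    "transcript-consistent",
    "no-transcript",
    "miRNA-candidate",
    "other-post-transcriptional",
)


@dataclass
class CorrelationResult:
    per_sample: pd.DataFrame  # sample, group, r, n_features, flagged
    group_means: pd.Series
    anova_f: float
    anova_p: float


def per_sample_correlation(
    protein: OmicsMatrix,
    transcript: OmicsMatrix,
    pairing: dict | None = None,
    min_features: int = 100,
) -> CorrelationResult:
    """Pearson correlation of log10 protein vs log10 transcript abundance
    per sample, over features positive in both layers, followed by a
    one-way ANOVA of the per-sample correlations across age groups.

    ``pairing`` maps sample ids to (protein column, transcript column);
    by default columns with identical names are matched. Samples with
    fewer than ``min_features`` shared positive features are flagged and
    excluded from the ANOVA.
    """
    if pairing is None:
        shared_samples = protein.samples.intersection(transcript.samples)
        pairing = {s: (s, s) for s in shared_samples}
    if not pairing:
        raise ValueError("no paired samples")
    shared_features = protein.features.intersection(transcript.features)
    groups = protein.groups()

    rows = []
    for sample, (p_col, t_col) in pairing.items():
        p = protein.data.loc[shared_features, p_col].to_numpy(dtype=float)
        t = transcript.data.loc[shared_features, t_col].to_numpy(dtype=float)
        mask = (p > 0) & (t > 0)
        n = int(mask.sum())
        if n < min_features:
            log.warning("sample %s: only %d shared positive features; flagged", sample, n)
            rows.append((sample, groups.get(sample), np.nan, n, True))
            continue
        r = float(stats.pearsonr(np.log10(p[mask]), np.log10(t[mask]))[0])
        rows.append((sample, groups.get(sample), r, n, False))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "group", "r", "n_features", "flagged"]
    ).set_index("sample")

    valid = per_sample[~per_sample["flagged"]]
    group_means = valid.groupby("group", sort=False)["r"].mean()
    by_group = [g["r"].to_numpy() for _, g in valid.groupby("group", sort=False)]
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group):
        if all(np.allclose(v, by_group[0][0]) for v in by_group):
            f, p = 0.0, 1.0  # all correlations identical
        else:
            f, p = stats.f_oneway(*by_group)
    else:
        f, p = np.nan, np.nan
    return CorrelationResult(per_sample, group_means, float(f), float(p))


def concordance_quadrants(
    protein_de: pd.DataFrame,
    transcript_de: pd.DataFrame,
    adj_p_threshold: float = 0.05,
) -> dict:
    """Quadrant counts and fold-change correlation for features
    significant in both layers (adj p below threshold in each).

    Quadrant keys are ``"<transcript sign>/<protein sign>"`` with signs
    ``up``/``down``. Pearson r over the (transcript fc, protein fc) pairs
    is reported; with fewer than 3 jointly significant features it is
    undefined (None).
    """
    shared = protein_de.index.intersection(transcript_de.index)
    p_de = protein_de.loc[shared]
    t_de = transcript_de.loc[shared]
    both = (p_de["adj_p"] < adj_p_threshold) & (t_de["adj_p"] < adj_p_threshold)
    t_fc = t_de.loc[both, "log2fc"]
    p_fc = p_de.loc[both, "log2fc"]

    def side(x):
        return "up" if x > 0 else "down"

    counts = {f"{a}/{b}": 0 for a in ("up", "down") for b in ("up", "down")}
    members: dict[str, list] = {k: [] for k in counts}
    for feature in t_fc.index:
        key = f"{side(t_fc[feature])}/{side(p_fc[feature])}"
        counts[key] += 1
        members[key].append(feature)
    if both.sum() >= 3:
        r = float(stats.pearsonr(t_fc, p_fc)[0])
    else:
        r = None
    return {
        "counts": counts,
        "members": members,
        "n_joint": int(both.sum()),
        "r": r,
    }


def classify_mechanism(
    protein_de: pd.DataFrame,
    transcript_de: pd.DataFrame,
    transcript_detected: set,
    mirna_de: pd.DataFrame,
    target_map: dict,
    adj_p: float = 0.05,
) -> pd.DataFrame:
    """Assign each age-affected protein (protein adj p < threshold) to one
    of five mutually exclusive regulatory-mechanism classes.

    Decision order: transcript not detected; transcript significant with
    the same fold-change sign; transcript same sign but not significant;
    protein down-regulated and targeted by an up-regulated miRNA
    (log2 fc > 0, adj p < threshold); everything else is attributed to
    other post-transcriptional regulation.
    """
    affected = protein_de[protein_de["adj_p"] < adj_p]
    transcript_detected = set(transcript_detected)

    up_mirnas = mirna_de[(mirna_de["log2fc"] > 0) & (mirna_de["adj_p"] < adj_p)].index
    mirna_targeted: dict[str, list] = {}
    for mirna in up_mirnas:
        for gene in target_map.get(mirna, ()):
            mirna_targeted.setdefault(gene, []).append(mirna)

    rows = []
    for feature, row in affected.iterrows():
        p_fc, p_adj = row["log2fc"], row["adj_p"]
        in_transcriptome = feature in transcript_de.index
        if not in_transcriptome and feature in transcript_detected:
            raise ValueError(
                f"feature {feature!r} marked detected but absent from the "
                "transcript differential table"
            )
        t_fc = transcript_de["log2fc"].get(feature, np.nan)
        t_adj = transcript_de["adj_p"].get(feature, np.nan)
        matched = mirna_targeted.get(feature, [])
        if feature not in transcript_detected:
            cls = "no-transcript"
        elif t_adj < adj_p and np.sign(t_fc) == np.sign(p_fc) != 0:
            cls = "concordant-significant"
        elif np.sign(t_fc) == np.sign(p_fc) != 0:
            cls = "transcript-consistent"
        elif p_fc < 0 and matched:
            cls = "miRNA-candidate"
        else:
            cls = "other-post-transcriptional"
        rows.append(
            (feature, cls, p_fc, p_adj, t_fc, t_adj, ";".join(matched))
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "mechanism_class",
            "protein_log2fc",
            "protein_adj_p",
            "transcript_log2fc",
            "transcript_adj_p",
            "matched_mirnas",
        ],
    ).set_index("feature_id")
    fractions = (
        out["mechanism_class"].value_counts(normalize=True).reindex(MECHANISM_ORDER).fillna(0.0)
    )
    out.attrs["class_fractions"] = fractions.to_dict()
    return out


def fold_change_of_means(
    matrix: OmicsMatrix,
    group_a: str,
    group_b: str,
    pseudo: float = 0.5,
) -> pd.Series:
    """log2 ratio of per-group mean abundances (a over b); the generic
    fold-change utility used for marker and footprint-style comparisons."""
    a = matrix.data[matrix.samples_in_group(group_a)].mean(axis=1)
    b = matrix.data[matrix.samples_in_group(group_b)].mean(axis=1)
    return np.log2((a + pseudo) / (b + pseudo)).rename(f"{group_a}vs{group_b}")
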