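"""PSM-level TMT processing, protein-group summarization, in-silico
tryptic digestion, and the precursor-intensity splitting route to iBAQ.

The processing chain mirrors standard isobaric-label practice: PSMs are
filtered on identity and reporter quality, reporter intensities are log2
transformed and median-centered per channel, and protein groups are
summarized as the median over complete proteotypic peptide observations.
iBAQ values are obtained by distributing each peptide's precursor (MS1)
area over the reporter channels in proportion to its TMT ratios, summing
per protein, and dividing by the count of theoretically observable
tryptic peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .io import reporter_columns

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# In-silico digestion


@dataclass(frozen=True)
class DigestionRule:
    """Tryptic digestion: cleave C-terminal to K/R unless followed by P.

    ``missed_cleavages`` is 0 for observable-peptide counting; the length
    window is inclusive.
    """

    cleavage_residues: frozenset = frozenset({"K", "R"})
    suppress_before: str = "P"
    missed_cleavages: int = 0
    min_length: int = 8
    max_length: int = 25


def tryptic_peptides(sequence: str, rule: DigestionRule = DigestionRule()) -> list[str]:
    """Fully tryptic fragments of ``sequence`` (no missed cleavages).

    Unknown residues (X/B/Z/U...) are treated as non-cleaving; fragments
    containing them are still returned.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        return []
    fragments = []
    start = 0
    for i, residue in enumerate(sequence):
        at_end = i == len(sequence) - 1
        cleave = (
            residue in rule.cleavage_residues
            and not at_end
            and sequence[i + 1] != rule.suppress_before
        )
        if cleave:
            fragments.append(sequence[start : i + 1])
            start = i + 1
    fragments.append(sequence[start:])
    return [f for f in fragments if f]


def digest_and_count_observable(sequence: str, rule: DigestionRule = DigestionRule()) -> int:
    """Count distinct fully tryptic peptides with length inside the rule's
    window — the iBAQ denominator."""
    peptides = {
        p for p in tryptic_peptides(sequence, rule) if rule.min_length <= len(p) <= rule.max_length
    }
    return len(peptides)


# ---------------------------------------------------------------------------
# PSM filtering


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    n_reverse: int = 0
    n_contaminant: int = 0
    n_low_score: int = 0
    n_low_reporter: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_psms(
    table: pd.DataFrame,
    min_score: float = 15.0,
    min_reporter: float = 1e3,
) -> tuple[pd.DataFrame, FilterReport]:
    """Discard PSMs mapping to reverse or contaminant hits, scoring below
    ``min_score``, or with reporter intensities below ``min_reporter`` in
    all channels. Removal counts are reported per criterion (a PSM may
    fail several)."""
    if len(table) == 0:
        raise ValueError("empty PSM table")
    rep_cols = reporter_columns(table)
    reporters = table[rep_cols].to_numpy(dtype=float)
    reverse = table["is_reverse"].astype(bool).to_numpy()
    contaminant = table["is_contaminant"].astype(bool).to_numpy()
    low_score = table["search_score"].to_numpy(dtype=float) < min_score
    low_reporter = (reporters < min_reporter).all(axis=1)
    keep = ~(reverse | contaminant | low_score | low_reporter)
    report = FilterReport(
        n_input=len(table),
        n_retained=int(keep.sum()),
        n_reverse=int(reverse.sum()),
        n_contaminant=int(contaminant.sum()),
        n_low_score=int(low_score.sum()),
        n_low_reporter=int(low_reporter.sum()),
    )
    if report.n_retained == 0:
        raise ValueError(f"all PSMs removed by filtering: {report.as_dict()}")
    return table.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Protein-group summarization


@dataclass
class ProteinGroupMatrix:
    """Protein group x channel log2 abundances with peptide-support counts."""

    data: pd.DataFrame
    n_unique_peptides: pd.Series
    n_observable_peptides: pd.Series | None = None

    def to_omics(self, meta: pd.DataFrame | None = None) -> OmicsMatrix:
        return OmicsMatrix(self.data, kind="log2", meta=meta)


def summarize_protein_groups(
    table: pd.DataFrame,
    min_unique_peptides: int = 2,
) -> ProteinGroupMatrix:
    """Summarize filtered PSMs into protein-group log2 abundances.

    Reporter intensities are log2 transformed and median-centered per
    channel; only proteotypic (unique) peptides complete in every channel
    are used; each protein group takes the median over its peptide
    observations and must be supported by at least ``min_unique_peptides``
    distinct unique peptides.
    """
    rep_cols = reporter_columns(table)
    unique = table[table["is_unique_peptide"].astype(bool)]
    reporters = unique[rep_cols].to_numpy(dtype=float)
    complete = (reporters > 0).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("excluded %d PSMs with missing/zero channels", n_dropped)
    unique = unique.loc[complete]
    if len(unique) == 0:
        raise ValueError("no complete unique-peptide PSMs to summarize")
    values = np.log2(unique[rep_cols].to_numpy(dtype=float))
    values = values - np.median(values, axis=0, keepdims=True)  # per-channel centering
    frame = pd.DataFrame(values, columns=rep_cols, index=unique.index)
    frame["protein_group_id"] = unique["protein_group_id"].to_numpy()
    frame["peptide_sequence"] = unique["peptide_sequence"].to_numpy()

    summarized = frame.groupby("protein_group_id")[rep_cols].median()
    support = frame.groupby("protein_group_id")["peptide_sequence"].nunique()
    enough = support[support >= min_unique_peptides].index
    dropped = support.index.difference(enough)
    if len(dropped):
        log.info("dropped %d proteins with < %d unique peptides", len(dropped), min_unique_peptides)
    summarized = summarized.loc[enough]
    summarized.index.name = "protein_group_id"
    return ProteinGroupMatrix(summarized, support.loc[enough])


# ---------------------------------------------------------------------------
# Precursor splitting and iBAQ


def split_precursor_to_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Distribute each peptide's total precursor (MS1) area over TMT
    channels.

    Per peptide, the channel ratio is the median over its PSMs of
    reporter_c / sum(reporters), renormalized to sum 1 so that the split
    conserves the precursor total; after splitting, channel intensities
    are multiplied by the per-channel median peptide ratio to correct for
    sampling aberrations. Peptides whose PSMs all have zero reporter sum
    are dropped.

    Returns a peptide-level table with channel intensity columns plus
    ``precursor_total``, ``protein_group_id`` and ``is_unique_peptide``.
    """
    rep_cols = reporter_columns(table)
    reporters = table[rep_cols].to_numpy(dtype=float)
    totals = reporters.sum(axis=1)
    usable = totals > 0
    if not usable.any():
        raise ValueError("no PSMs with positive reporter sums")
    work = table.loc[usable].copy()
    ratios = reporters[usable] / totals[usable, None]
    for j, col in enumerate(rep_cols):
        work[f"ratio_{col}"] = ratios[:, j]
    ratio_cols = [f"ratio_{c}" for c in rep_cols]

    grouped = work.groupby("peptide_sequence")
    peptide_ratio = grouped[ratio_cols].median()
    peptide_ratio = peptide_ratio.div(peptide_ratio.sum(axis=1), axis=0)
    precursor_total = grouped["precursor_intensity"].sum()
    protein = grouped["protein_group_id"].first()
    is_unique = grouped["is_unique_peptide"].first().astype(bool)

    split = peptide_ratio.mul(precursor_total, axis=0)
    split.columns = rep_cols
    # per-channel sampling-aberration correction: multiply by the median
    # of the peptide TMT ratios in that channel
    correction = peptide_ratio.median(axis=0).to_numpy()
    corrected = split * correction[None, :]
    out = corrected.copy()
    out["precursor_total"] = precursor_total
    out["protein_group_id"] = protein
    out["is_unique_peptide"] = is_unique
    for col in rep_cols:
        out[f"uncorrected_{col}"] = split[col]
    out.index.name = "peptide_sequence"
    return out.reset_index()


def compute_ibaq(
    split_table: pd.DataFrame,
    observable_counts: pd.Series | dict,
    unique_only: bool = True,
    normalize: bool = True,
) -> OmicsMatrix:
    """iBAQ per protein and channel: summed unique-peptide channel
    intensities divided by the count of observable tryptic peptides, then
    median-normalized across samples (each channel scaled so its median
    iBAQ equals 1).

    Proteins with zero observable peptides cannot be normalized by the
    formula and are excluded (logged).
    """
    observable = pd.Series(observable_counts, dtype=float)
    rep_cols = reporter_columns(split_table)
    work = split_table
    if unique_only:
        work = work[work["is_unique_peptide"].astype(bool)]
    summed = work.groupby("protein_group_id")[rep_cols].sum()
    missing = summed.index.difference(observable.index)
    if len(missing):
        raise ValueError(f"no observable-peptide count for proteins: {list(missing)[:5]}")
    counts = observable.loc[summed.index]
    zero = counts == 0
    if zero.any():
        log.info("excluded %d proteins with zero observable peptides", int(zero.sum()))
    summed = summed.loc[~zero]
    ibaq = summed.div(counts[~zero], axis=0)
    if normalize:
        medians = ibaq.median(axis=0)
        if (medians <= 0).any():
            raise ValueError("non-positive channel median; cannot median-normalize")
        ibaq = ibaq.div(medians, axis=1)
    ibaq.index.name = "protein_group_id"
    return OmicsMatrix(ibaq, kind="intensity")
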