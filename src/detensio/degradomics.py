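"""Substrate discovery and semi-tryptic cleavage-motif evidence.

Two halves of a terminal-degradomics workflow, downstream of the search
engine:

* **Protein level** — from a protein intensity table (proteins x samples,
  treated vs vehicle) compute per-protein log2 fold changes on group means
  of log2 abundance, Welch two-sample t-test p-values and Benjamini-
  Hochberg q-values, and call substrates with the strict filter
  log2fc > 0.4 and q < 0.1.

* **Peptide level** — classify each identified peptide's termini against
  tryptic specificity (cleavage after K/R, peptide at a protein terminus
  also conforms).  A peptide is tryptic (both termini conform),
  semi-tryptic (exactly one) or non-tryptic (none).  For every
  non-conforming terminus the P1 residue (immediately N-terminal to the
  cleavage site) is extracted; Leu or Ile at P1 is the favorable
  collagenase-1 motif (MEROPS M10.001 preference).

Protein coordinates are 1-based inclusive throughout, the proteomics
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityTable",
    "DigestRule",
    "PeptideEvidence",
    "FAVORABLE_P1",
    "welch_ttest",
    "bh_qvalues",
    "substrate_stats",
    "filter_substrates",
    "cleavage_sites",
    "digest",
    "classify_terminal_specificity",
    "cleavage_motif_check",
    "summarize_cleavage_evidence",
]

#: Collagenase-1 favors Leu/Ile at P1 (MEROPS M10.001 specificity matrix).
FAVORABLE_P1 = frozenset({"L", "I"})

_AA = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Protein-level statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityTable:
    """Protein abundance matrix with a treated/vehicle sample grouping.

    ``abundance`` is proteins x samples; zeros and NaN are treated as
    missing.  ``groups`` maps each sample (column) to "treated" or
    "vehicle".
    """

    abundance: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        groups = pd.Series(self.groups)
        object.__setattr__(self, "groups", groups)
        missing = set(self.abundance.columns) - set(groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        labels = set(groups.loc[list(self.abundance.columns)])
        if not labels <= {"treated", "vehicle"}:
            raise ValueError("group labels must be 'treated' or 'vehicle'")
        for lab in ("treated", "vehicle"):
            if (groups.loc[list(self.abundance.columns)] == lab).sum() < 2:
                raise ValueError(f"need >= 2 samples in group {lab!r}")
        if (self.abundance.fillna(0).to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    def log2_by_group(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Log2-transformed treated and vehicle sub-tables (0 -> NaN)."""
        x = self.abundance.replace(0, np.nan)
        cols = list(self.abundance.columns)
        lab = self.groups.loc[cols]
        treated = np.log2(x.loc[:, [c for c in cols if lab[c] == "treated"]])
        vehicle = np.log2(x.loc[:, [c for c in cols if lab[c] == "vehicle"]])
        return treated, vehicle


def welch_ttest(a: np.ndarray, b: np.ndarray, eps: float = 1e-12) -> float:
    """Two-sided Welch t-test p-value with a zero-variance epsilon guard.

    With both group variances zero the standard error collapses; the guard
    substitutes ``eps`` so identical means give p = 1 and distinct means
    give p -> 0 instead of NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 values per group")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        se2 = eps
        df = n1 + n2 - 2
    else:
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    tstat = (a.mean() - b.mean()) / math.sqrt(se2)
    from scipy import stats as _st

    return float(2.0 * _st.t.sf(abs(tstat), df))


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def substrate_stats(table: IntensityTable) -> pd.DataFrame:
    """Per-protein log2 fold change, Welch p-value and BH q-value.

    Fold change is the difference of group means of log2 abundance
    (log2(treated/vehicle)).  Proteins with fewer than 2 non-missing values
    in either group are excluded (reported in the ``excluded`` attribute of
    the returned frame).  q-values are BH-adjusted over all tested
    proteins.
    """
    treated, vehicle = table.log2_by_group()
    rows = []
    excluded = []
    for protein in table.abundance.index:
        a = treated.loc[protein].dropna().to_numpy()
        b = vehicle.loc[protein].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            excluded.append(protein)
            continue
        rows.append(
            {
                "protein": protein,
                "log2fc": float(a.mean() - b.mean()),
                "p_value": welch_ttest(a, b),
                "n_treated": a.size,
                "n_vehicle": b.size,
            }
        )
    stats = pd.DataFrame(
        rows, columns=["protein", "log2fc", "p_value", "n_treated", "n_vehicle"]
    ).set_index("protein")
    stats["q_value"] = bh_qvalues(stats["p_value"].to_numpy())
    stats.attrs["excluded"] = excluded
    return stats


def filter_substrates(
    stats: pd.DataFrame, fc_min: float = 0.4, q_max: float = 0.1
) -> pd.DataFrame:
    """Substrates passing log2fc > fc_min AND q < q_max (strict), sorted.

    Strict inequalities are the default reading of the published filter;
    both cutoffs are parameters so the inclusive variant is reproducible
    too.  Result is ordered by descending log2fc; the input frame gains a
    boolean ``passes`` column.
    """
    passes = (stats["log2fc"] > fc_min) & (stats["q_value"] < q_max)
    stats = stats.copy()
    stats["passes"] = passes
    return stats.loc[passes].sort_values("log2fc", ascending=False)


# ---------------------------------------------------------------------------
# Peptide-level terminal specificity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigestRule:
    """Protease specificity: cleave after ``cleave_after`` residues.

    Defaults are trypsin (after K/R) with one missed cleavage and no
    proline suppression, matching the common semi-trypsin search setting.
    """

    cleave_after: frozenset[str] = frozenset({"K", "R"})
    suppress_before_proline: bool = False
    max_missed_cleavages: int = 1

    def __post_init__(self) -> None:
        ca = frozenset(self.cleave_after)
        object.__setattr__(self, "cleave_after", ca)
        if not ca:
            raise ValueError("cleave_after must be non-empty")


@dataclass
class PeptideEvidence:
    """A peptide located in its parent protein with terminal classification.

    ``start``/``end`` are 1-based inclusive.  ``p1_residues`` holds the P1
    residue of each non-conforming terminus (N-terminal boundary first when
    both are non-conforming); ``favorable`` is True when any P1 is Leu or
    Ile.
    """

    sequence: str
    protein_id: str
    start: int
    end: int
    terminal_class: str = "tryptic"
    p1_residues: list[str] = field(default_factory=list)
    favorable: bool = False
    n_term_conforms: bool = True
    c_term_conforms: bool = True


def cleavage_sites(protein_seq: str, rule: DigestRule) -> list[int]:
    """0-based positions i such that the bond after residue i is cleaved."""
    sites = []
    n = len(protein_seq)
    for i, aa in enumerate(protein_seq[:-1]):
        if aa in rule.cleave_after:
            if rule.suppress_before_proline and protein_seq[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(protein_seq: str, rule: DigestRule | None = None) -> list[tuple[int, int]]:
    """Fully-tryptic peptides as 1-based inclusive (start, end) spans.

    Peptides span up to ``max_missed_cleavages`` internal cleavage sites.
    """
    rule = rule or DigestRule()
    n = len(protein_seq)
    bounds = [0] + [i + 1 for i in cleavage_sites(protein_seq, rule)] + [n]
    peptides = []
    for j in range(len(bounds) - 1):
        for k in range(j + 1, min(j + 2 + rule.max_missed_cleavages, len(bounds))):
            peptides.append((bounds[j] + 1, bounds[k]))
    return peptides


def _terminus_conformance(
    protein_seq: str, start: int, end: int, rule: DigestRule
) -> tuple[bool, bool]:
    """(N-term conforms, C-term conforms) for a 1-based inclusive span."""
    n = len(protein_seq)
    if start == 1:
        n_ok = True
    else:
        prev = protein_seq[start - 2]
        n_ok = prev in rule.cleave_after and not (
            rule.suppress_before_proline and protein_seq[start - 1] == "P"
        )
    if end == n:
        c_ok = True
    else:
        last = protein_seq[end - 1]
        c_ok = last in rule.cleave_after and not (
            rule.suppress_before_proline and protein_seq[end] == "P"
        )
    return n_ok, c_ok


def classify_terminal_specificity(
    sequence: str,
    protein_id: str,
    start: int,
    end: int,
    protein_seq: str,
    rule: DigestRule | None = None,
) -> PeptideEvidence:
    """Classify a located peptide as tryptic / semi_tryptic / non_tryptic.

    A terminus conforms if the residue preceding it is in the cleavage set
    (or the terminus coincides with a protein terminus).  Raises if the
    peptide sequence does not match the protein at the stated coordinates.
    """
    rule = rule or DigestRule()
    if not (1 <= start <= end <= len(protein_seq)):
        raise ValueError("peptide coordinates outside protein")
    if protein_seq[start - 1 : end] != sequence:
        raise ValueError(
            f"peptide {sequence!r} does not match protein {protein_id} "
            f"at positions {start}..{end}"
        )
    n_ok, c_ok = _terminus_conformance(protein_seq, start, end, rule)
    cls = {2: "tryptic", 1: "semi_tryptic", 0: "non_tryptic"}[n_ok + c_ok]
    ev = PeptideEvidence(
        sequence=sequence,
        protein_id=protein_id,
        start=start,
        end=end,
        terminal_class=cls,
        n_term_conforms=n_ok,
        c_term_conforms=c_ok,
    )
    if cls != "tryptic":
        ev = cleavage_motif_check(ev, protein_seq)
    return ev


def cleavage_motif_check(
    evidence: PeptideEvidence, protein_seq: str
) -> PeptideEvidence:
    """Attach P1 residues and the favorable Leu/Ile-motif flag.

    For a non-conforming N-terminus the P1 residue sits in the protein just
    before the peptide start; for a non-conforming C-terminus it is the
    peptide's own last residue.  A non-conforming N-terminus at start = 1
    (only possible under non-default rules) has no P1 and can never be
    favorable by that boundary.
    """
    if evidence.terminal_class == "tryptic":
        evidence.p1_residues = []
        evidence.favorable = False
        return evidence
    p1s: list[str] = []
    if not evidence.n_term_conforms and evidence.start > 1:
        p1s.append(protein_seq[evidence.start - 2])
    if not evidence.c_term_conforms:
        p1s.append(evidence.sequence[-1])
    evidence.p1_residues = p1s
    evidence.favorable = any(r in FAVORABLE_P1 for r in p1s)
    return evidence


def summarize_cleavage_evidence(
    evidences: list[PeptideEvidence], protein_id: str | None = None
) -> dict:
    """Counts of total / semi-or-non-tryptic / favorable peptides.

    Mirrors the per-substrate summary "N peptides, of which k semi-/non-
    tryptic, of which m with favorable P1".  Optionally restricted to one
    protein.
    """
    evs = [
        e
        for e in evidences
        if protein_id is None or e.protein_id == protein_id
    ]
    n_semi = sum(e.terminal_class in ("semi_tryptic", "non_tryptic") for e in evs)
    n_fav = sum(
        e.favorable and e.terminal_class in ("semi_tryptic", "non_tryptic")
        for e in evs
    )
    return {
        "n_total": len(evs),
        "n_semi_or_non": int(n_semi),
        "n_favorable": int(n_fav),
    }
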