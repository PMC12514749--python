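"""Cohort-level analytics over the packaged case fixtures.

The fixtures ship the published cohort tables: the 31-case discordance
table (one row per fusion-positive case on which the three callers
disagreed, with the RT-PCR validation result), the per-class alteration
counts for the 342-patient cohort, and the per-junction counts for the
nine observed KIAA1549::BRAF exon-exon junctions. All percentages are
recomputed from the integer counts at load time — stored percents are
never trusted — using half-up rounding at each class's printed precision,
because published rounding is not always reconstructible from the counts
(the fixture's ``note`` column records such cases).

The triage planner encodes the cost-effective diagnostic route: tumors in
locations where KIAA1549::BRAF and BRAF V600E dominate (posterior fossa,
spinal, midline, optic pathway, cerebellum) get targeted PCR assays first
and RNA NGS only if those are negative; hemispheric tumors go straight to
NGS; a DNET histology prepends the FGFR1 kinase-domain-duplication RT-PCR.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd

from .models import ValidationError

MISSED = "X"
NOT_DONE = "ND"

CALLER_COLUMNS = ("archer", "arriba", "starfusion")
_CALLER_ALIASES = {"archer_like": "archer", "arriba_like": "arriba",
                   "starfusion_like": "starfusion"}

N_FUSION_POSITIVE = 88   # fusion-positive cases in the 115-case NGS sub-cohort
COHORT_SIZE = 342        # patients with material sufficient for profiling

ALTERATION_CLASSES = frozenset({
    "KIAA1549::BRAF", "BRAF_V600E", "BRAF_fusion_noncanonical", "BRAF_SNV_other",
    "FGFR1::TACC1", "KDD_FGFR1", "FGFR1_SNV", "FGFR2_fusion", "FGFR3::TACC3",
    "other_RTK_fusion", "KRAS_SNV", "PDGFRA_SNV", "MYB", "MYBL1", "IDH1_SNV"})

LOCATIONS = ("posterior_fossa", "hemispheric", "midline", "optic_pathway",
             "spinal", "cerebellum", "other")

# diagnostic steps used by the triage planner
STEP_RTPCR_KIAA = "rtpcr_kiaa1549_braf"
STEP_PCR_V600E = "pcr_braf_v600e"
STEP_RTPCR_KDD = "rtpcr_kdd_fgfr1"
STEP_NGS = "ngs"

_TARGETED_FIRST = {"posterior_fossa", "spinal", "midline", "optic_pathway", "cerebellum"}
_NGS_FIRST = {"hemispheric", "other"}


class FixtureError(ValidationError):
    """A packaged fixture fails its shape or vocabulary checks."""


# ---------------------------------------------------------------------------
# fixture loading
# ---------------------------------------------------------------------------

def _read_fixture(name: str) -> pd.DataFrame:
    path = resources.files("junctionscope.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def load_fixture(name: str) -> pd.DataFrame:
    """Load and validate one of the packaged cohort fixtures.

    ``table1`` — 31 discordant cases x (diagnosis, 3 callers, RT-PCR);
    ``cohort_counts`` — per-alteration-class counts out of 342;
    ``kiaa_junctions`` — the 9 KIAA1549::BRAF junction labels with counts.
    """
    if name == "table1":
        df = _read_fixture("table1.tsv")
        expected = ["dg", "archer", "arriba", "starfusion", "rtpcr"]
        if list(df.columns) != expected:
            raise FixtureError(f"table1: columns {list(df.columns)} != {expected}")
        if len(df) != 31:
            raise FixtureError(f"table1: expected 31 rows, found {len(df)}")
        calls = df[list(CALLER_COLUMNS)]
        if bool((calls == MISSED).all(axis=1).any()):
            raise FixtureError("table1: a row with no detection by any caller")
        return df
    if name == "cohort_counts":
        df = _read_fixture("cohort_counts.tsv")
        df["n"] = df["n"].astype(int)
        df["decimals"] = df["decimals"].astype(int)
        unknown = set(df["class"]) - ALTERATION_CLASSES
        if unknown:
            raise FixtureError(f"cohort_counts: classes outside vocabulary: {sorted(unknown)}")
        if int(df["n"].sum()) > COHORT_SIZE:
            raise FixtureError("cohort_counts: counts exceed cohort size")
        return df
    if name == "kiaa_junctions":
        df = _read_fixture("kiaa_junctions.tsv")
        df["n"] = df["n"].astype(int)
        if len(df) != 9:
            raise FixtureError(f"kiaa_junctions: expected 9 rows, found {len(df)}")
        if df["label"].duplicated().any():
            raise FixtureError("kiaa_junctions: duplicated junction labels")
        return df
    raise FixtureError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# call matrix and caller sensitivity
# ---------------------------------------------------------------------------

def build_call_matrix(table1: pd.DataFrame,
                      n_total_fusion_positive: int = N_FUSION_POSITIVE) -> pd.DataFrame:
    """Reconstruct the full fusion-positive call matrix.

    The published discordance table lists only the cases on which callers
    disagreed; the remaining fusion-positive cases were detected by all
    three callers. Those rows are appended as explicitly flagged
    ``synthetic_padding`` reconstructions (each caller detected) so that
    downstream tables can exclude them.
    """
    n_discordant = len(table1)
    if n_total_fusion_positive < n_discordant:
        raise ValidationError(
            f"n_total_fusion_positive ({n_total_fusion_positive}) < discordant "
            f"rows ({n_discordant})")
    rows = []
    for i, r in table1.iterrows():
        truth = r["rtpcr"] if r["rtpcr"] != NOT_DONE else ""
        if not truth:  # fall back to the concordant caller label
            truth = next(v for v in (r["arriba"], r["archer"], r["starfusion"])
                         if v != MISSED)
        rows.append({"case_id": f"discordant_{i + 1:02d}", "dg": r["dg"],
                     "archer": r["archer"], "arriba": r["arriba"],
                     "starfusion": r["starfusion"], "truth": truth,
                     "synthetic_padding": False})
    for i in range(n_total_fusion_positive - n_discordant):
        label = f"concordant_fusion_{i + 1:02d}"
        rows.append({"case_id": f"concordant_{i + 1:02d}", "dg": "",
                     "archer": label, "arriba": label, "starfusion": label,
                     "truth": label, "synthetic_padding": True})
    return pd.DataFrame(rows)


def _caller_column(caller: str) -> str:
    col = _CALLER_ALIASES.get(caller, caller)
    if col not in CALLER_COLUMNS:
        raise ValidationError(f"unknown caller {caller!r}; want one of "
                              f"{CALLER_COLUMNS + tuple(_CALLER_ALIASES)}")
    return col


def caller_sensitivity(matrix: pd.DataFrame, caller: str) -> tuple[int, int, float]:
    """(detected, total, fraction) for one caller over the call matrix."""
    col = _caller_column(caller)
    detected = int((matrix[col] != MISSED).sum())
    total = len(matrix)
    return detected, total, detected / total


def overlap_counts(matrix: pd.DataFrame) -> dict[str, int]:
    """Venn-cell counts: rows detected by exactly each caller combination."""
    out: dict[str, int] = {}
    for r in range(1, len(CALLER_COLUMNS) + 1):
        for combo in combinations(CALLER_COLUMNS, r):
            key = "+".join(combo)
            mask = pd.Series(True, index=matrix.index)
            for c in CALLER_COLUMNS:
                hit = matrix[c] != MISSED
                mask &= hit if c in combo else ~hit
            out[key] = int(mask.sum())
    assert sum(out.values()) == len(matrix)
    return out


# ---------------------------------------------------------------------------
# frequencies and junction spectrum
# ---------------------------------------------------------------------------

def percent_half_up(count: int, total: int, decimals: int = 2) -> float:
    """100*count/total, rounded half-up to the requested printed precision."""
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        q, rounding=ROUND_HALF_UP))


def alteration_frequencies(cohort_counts: pd.DataFrame,
                           cohort_size: int = COHORT_SIZE) -> pd.DataFrame:
    """Per-class (count, percent-of-cohort) table; percents recomputed from
    counts at each class's printed precision, never stored independently."""
    if int(cohort_counts["n"].sum()) > cohort_size:
        raise ValidationError("counts exceed cohort size")
    df = cohort_counts.copy()
    df["percent"] = [percent_half_up(int(n), cohort_size, int(d))
                     for n, d in zip(df["n"], df["decimals"])]
    return df[["class", "n", "percent"]]


def junction_spectrum(kiaa_junctions: pd.DataFrame) -> tuple[int, int, str]:
    """(number of distinct junction labels, total cases, modal label)."""
    n_distinct = int(kiaa_junctions["label"].nunique())
    total = int(kiaa_junctions["n"].sum())
    modal = kiaa_junctions.loc[kiaa_junctions["n"].idxmax(), "label"]
    return n_distinct, total, str(modal)


def fgfr_aggregate(cohort_counts: pd.DataFrame) -> int:
    """Total FGFR-altered patients (fusions, duplications and hotspot SNVs)."""
    fgfr = {"FGFR1::TACC1", "KDD_FGFR1", "FGFR1_SNV", "FGFR2_fusion", "FGFR3::TACC3"}
    return int(cohort_counts.loc[cohort_counts["class"].isin(fgfr), "n"].sum())


# ---------------------------------------------------------------------------
# diagnostic triage
# ---------------------------------------------------------------------------

def triage_route(location: str, histology_hint: Optional[str] = None,
                 prior_results: Optional[Mapping[str, bool]] = None) -> list[str]:
    """Ordered remaining test plan for one case.

    ``prior_results`` maps step name -> outcome; a positive prior result
    terminates the plan (nothing further is needed), a negative one skips
    that step.
    """
    if location not in LOCATIONS:
        raise ValidationError(f"unknown location {location!r}; want one of {LOCATIONS}")
    if location in _TARGETED_FIRST:
        plan = [STEP_RTPCR_KIAA, STEP_PCR_V600E, STEP_NGS]
    else:
        plan = [STEP_NGS]
    if histology_hint is not None and histology_hint.upper() == "DNET":
        plan = [STEP_RTPCR_KDD] + [s for s in plan if s != STEP_RTPCR_KDD]
    prior = dict(prior_results or {})
    remaining = []
    for step in plan:
        if step in prior:
            if prior[step]:
                return []
            continue  # negative prior: step already done
        remaining.append(step)
    return remaining
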