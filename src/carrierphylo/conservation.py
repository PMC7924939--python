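"""Per-residue conservation scoring and specificity-site nomination.

Shannon entropy, H = -sum p_i log2 p_i over the residue frequencies of an
alignment column, is computed three ways for every column where a chosen
reference sequence has a residue: over the clade-A rows, the clade-B rows,
and all rows.  Columns are mapped to 1-based positions in the ungapped
reference (the study's convention: residues numbered by the yeast PIC2
sequence), and each position is then classified:

* shared_conserved — low entropy in both clades with the same consensus;
  a candidate requirement of both transport functions.
* A_specific / B_specific — low entropy in one clade while the other clade
  is variable or fixed for a different residue; a candidate
  substrate-specificity determinant (e.g. Cys in PIC2-like versus Thr in
  MIR1-like at position 44).
* variable, or low_coverage when a clade has mostly gaps at the column.

Entropy uses base 2 (bits) by default with gaps and 'X' excluded from the
frequency counts; both choices are configurable.
"""

from __future__ import annotations

import math
from collections import Counter

import pandas as pd

from .io_formats import GAP, UNKNOWN, Alignment

SHARED = "shared_conserved"
A_SPECIFIC = "A_specific"
B_SPECIFIC = "B_specific"
VARIABLE = "variable"
LOW_COVERAGE = "low_coverage"

#: Reference positions highlighted in the study's per-site residue panels,
#: in yeast PIC2 numbering.  A convenience default for site-state extraction.
DEFAULT_SITE_PANEL = (21, 29, 33, 44, 47, 48, 86, 90, 124, 127,
                      176, 182, 225, 230, 268, 275)


class ConservationError(ValueError):
    pass


def column_entropy(column: str, base: float = 2.0,
                   gap_policy: str = "exclude") -> float | None:
    """Shannon entropy of one alignment column.

    ``gap_policy="exclude"`` drops gaps and 'X' before computing
    frequencies; ``"symbol"`` keeps the gap as a 21st character state
    ('X' is always treated as missing).  Returns ``None`` when the policy
    removes every symbol (the low-coverage sentinel).
    """
    if not column:
        raise ConservationError("empty column")
    if gap_policy == "exclude":
        symbols = [c for c in column if c not in (GAP, UNKNOWN)]
    elif gap_policy == "symbol":
        symbols = [c for c in column if c != UNKNOWN]
    else:
        raise ConservationError(f"unknown gap policy {gap_policy!r}")
    if not symbols:
        return None
    n = len(symbols)
    h = 0.0
    for count in Counter(symbols).values():
        p = count / n
        h -= p * math.log(p, base)
    return abs(h)  # avoid -0.0


def _consensus(column: str) -> tuple[str | None, float]:
    symbols = [c for c in column if c not in (GAP, UNKNOWN)]
    if not symbols:
        return None, 0.0
    (sym, count), = Counter(symbols).most_common(1)
    return sym, count / len(symbols)


def reference_column_map(aln: Alignment, reference_id: str) -> list[int]:
    """0-based alignment columns where the reference is non-gap, in order.

    Index ``i`` of the result is reference position ``i + 1``; the map is a
    bijection between reference residues and reference-non-gap columns.
    """
    ref = aln.row(reference_id)
    return [i for i, c in enumerate(ref.residues) if c != GAP]


def entropy_profile(aln: Alignment, reference_id: str,
                    clades: dict[str, str], base: float = 2.0,
                    gap_policy: str = "exclude") -> pd.DataFrame:
    """Per-reference-position entropy table.

    ``clades`` maps every row id to "A" or "B" (rows mapped to anything
    else are counted only in the family-wide column).  Entropy is computed
    on clade-A rows, clade-B rows, and all rows; the clade consensus
    residue, its frequency, and non-gap coverage are recorded per clade.
    """
    if reference_id not in aln.ids():
        raise ConservationError(f"reference {reference_id!r} not in alignment")
    unknown = set(aln.ids()) - set(clades)
    if unknown:
        raise ConservationError(f"rows without clade label: {sorted(unknown)}")
    rows_a = [r for r in aln.rows if clades[r.id] == "A"]
    rows_b = [r for r in aln.rows if clades[r.id] == "B"]
    cols = reference_column_map(aln, reference_id)
    records = []
    for pos, col_idx in enumerate(cols, start=1):
        col_a = "".join(r.residues[col_idx] for r in rows_a)
        col_b = "".join(r.residues[col_idx] for r in rows_b)
        col_all = aln.column(col_idx)
        cons_a, freq_a = _consensus(col_a)
        cons_b, freq_b = _consensus(col_b)
        cov_a = (sum(1 for c in col_a if c != GAP) / len(col_a)) if col_a else 0.0
        cov_b = (sum(1 for c in col_b if c != GAP) / len(col_b)) if col_b else 0.0
        records.append({
            "ref_pos": pos,
            "column": col_idx,
            "H_cladeA": column_entropy(col_a, base, gap_policy) if col_a else None,
            "H_cladeB": column_entropy(col_b, base, gap_policy) if col_b else None,
            "H_all": column_entropy(col_all, base, gap_policy),
            "consensus_A": cons_a, "consensus_freq_A": round(freq_a, 4),
            "consensus_B": cons_b, "consensus_freq_B": round(freq_b, 4),
            "coverage_A": round(cov_a, 4), "coverage_B": round(cov_b, 4),
        })
    return pd.DataFrame.from_records(records)


def classify_positions(table: pd.DataFrame, threshold: float = 0.5,
                       min_coverage: float = 0.5) -> pd.DataFrame:
    """Add a ``category`` column; the entropy comparison is strict ``<``."""
    cats = []
    for _, row in table.iterrows():
        ha, hb = row["H_cladeA"], row["H_cladeB"]
        if (pd.isna(ha) or pd.isna(hb)
                or row["coverage_A"] < min_coverage
                or row["coverage_B"] < min_coverage):
            cats.append(LOW_COVERAGE)
            continue
        cons_a = ha < threshold
        cons_b = hb < threshold
        same = row["consensus_A"] == row["consensus_B"]
        if cons_a and cons_b and same:
            cats.append(SHARED)
        elif cons_a and (not cons_b or not same):
            cats.append(A_SPECIFIC)
        elif cons_b and (not cons_a or not same):
            cats.append(B_SPECIFIC)
        else:
            cats.append(VARIABLE)
    out = table.copy()
    out["category"] = cats
    return out


def extract_site_states(aln: Alignment, reference_id: str,
                        positions: list[int],
                        clades: dict[str, str] | None = None) -> pd.DataFrame:
    """Residue of every row at the named reference positions.

    One row per alignment sequence; gaps are reported as '-' (the panel's
    insertion/deletion marker).  Positions are 1-based in the ungapped
    reference sequence.
    """
    cols = reference_column_map(aln, reference_id)
    nref = len(cols)
    for p in positions:
        if not 1 <= p <= nref:
            raise ConservationError(
                f"position {p} outside reference length {nref}")
    records = []
    for r in aln.rows:
        rec = {"leaf": r.id}
        if clades is not None:
            rec["clade"] = clades.get(r.id, "")
        for p in positions:
            rec[f"pos{p}"] = r.residues[cols[p - 1]]
        records.append(rec)
    return pd.DataFrame.from_records(records)
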