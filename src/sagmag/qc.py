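"""Single-copy-gene QC and duplicated-element detection.

Completeness is the percentage of a marker set present at least once in a
genome; redundancy is the percentage present more than once.  Bins are
approved as MAGs when they carry at least 30 unique markers of a 36-gene
set with at most 2 of them in more than one copy.  Erroneously duplicated
assembly regions are located as maximal exact repeats of at least 100
bases shared by two distinct contigs of at least 1 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import logger


def completeness_redundancy(
    counts: Mapping[str, int] | pd.Series | Sequence[int],
    marker_set_size: int | None = None,
) -> tuple[float, float]:
    """(completeness %, redundancy %) from one genome's marker copy counts."""
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=int
    )
    size = marker_set_size if marker_set_size is not None else len(values)
    if size < 1:
        raise ValueError("marker set size must be >= 1")
    completeness = 100.0 * int((values >= 1).sum()) / size
    redundancy = 100.0 * int((values >= 2).sum()) / size
    return completeness, redundancy


def approve_bin(
    counts: Mapping[str, int] | pd.Series | Sequence[int],
    min_unique: int = 30,
    max_multicopy: int = 2,
    rule: str = "multicopy_markers",
) -> bool:
    """MAG approval rule on a 36-marker count row.

    Default reading: at least ``min_unique`` distinct markers present and
    at most ``max_multicopy`` markers occurring in more than a single
    copy.  ``rule="max_copies"`` applies the alternative reading where no
    marker may exceed ``max_multicopy`` copies.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=int
    )
    unique = int((values >= 1).sum())
    if rule == "multicopy_markers":
        return bool(unique >= min_unique and int((values >= 2).sum()) <= max_multicopy)
    if rule == "max_copies":
        return bool(unique >= min_unique and values.max(initial=0) <= max_multicopy)
    raise ValueError(f"rule must be 'multicopy_markers' or 'max_copies', got {rule!r}")


def qc_table(
    marker_counts: pd.DataFrame,
    approval_counts: pd.DataFrame | None = None,
    min_unique: int = 30,
    max_multicopy: int = 2,
) -> pd.DataFrame:
    """Completeness/redundancy per genome, plus approval if a 36-gene
    table is supplied (rows must match)."""
    rows = []
    for genome, row in marker_counts.iterrows():
        comp, red = completeness_redundancy(row.to_numpy())
        entry = {"genome_id": genome, "completeness": comp, "redundancy": red}
        if approval_counts is not None:
            entry["approved"] = approve_bin(
                approval_counts.loc[genome].to_numpy(), min_unique, max_multicopy
            )
        rows.append(entry)
    return pd.DataFrame(rows).set_index("genome_id")


# ---------------------------------------------------------------------------
# Duplicated elements (maximal exact cross-contig repeats)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicatedElement:
    """A maximal exact repeat shared by two contigs (0-based half-open)."""

    contig_a: str
    a_start: int
    a_end: int
    contig_b: str
    b_start: int
    b_end: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


def find_duplicated_elements(
    contigs: Mapping[str, str],
    min_element: int = 100,
    min_contig: int = 1000,
) -> list[DuplicatedElement]:
    """All maximal exact repeats >= ``min_element`` between distinct contigs.

    Shared ``min_element``-mers anchor candidate matches, which are
    extended to maximal length in both directions; each maximal repeat is
    reported once per contig pair.  Matches within a single contig are not
    reported.
    """
    eligible = {c: s for c, s in contigs.items() if len(s) >= min_contig}
    k = min_element
    anchors: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in eligible.items():
        for pos in range(len(seq) - k + 1):
            anchors.setdefault(seq[pos : pos + k], []).append((cid, pos))
    found: set[tuple[str, int, int, str, int, int]] = set()
    for occurrences in anchors.values():
        if len(occurrences) < 2:
            continue
        for i in range(len(occurrences)):
            for j in range(i + 1, len(occurrences)):
                (ca, pa), (cb, pb) = occurrences[i], occurrences[j]
                if ca == cb:
                    continue
                if ca > cb:
                    (ca, pa), (cb, pb) = (cb, pb), (ca, pa)
                sa, sb = eligible[ca], eligible[cb]
                left = 0
                while pa - left - 1 >= 0 and pb - left - 1 >= 0 and sa[pa - left - 1] == sb[pb - left - 1]:
                    left += 1
                right = k
                while pa + right < len(sa) and pb + right < len(sb) and sa[pa + right] == sb[pb + right]:
                    right += 1
                found.add((ca, pa - left, pa + right, cb, pb - left, pb + right))
    elements = [DuplicatedElement(*item) for item in sorted(found)]
    logger.info("find_duplicated_elements: %d maximal repeats", len(elements))
    return elements


def write_duplicated_elements(path, elements: Sequence[DuplicatedElement]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\ta_start\ta_end\tcontig_b\tb_start\tb_end\tlength\n")
        for e in elements:
            fh.write(
                f"{e.contig_a}\t{e.a_start}\t{e.a_end}\t{e.contig_b}"
                f"\t{e.b_start}\t{e.b_end}\t{e.length}\n"
            )
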