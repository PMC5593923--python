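"""Privileged-fragment scoring and election.

Each candidate fragment is scored with the privileged fragment index
PFI = f * a / T, where f is the number of library molecules containing
the fragment, a the number of active molecules containing it, and T the
library size.  Enrichment of the fragment in the active set relative to
a background library is tested with the one-tailed Fisher exact test on
the 2x2 table [[A, B], [C, D]] (matched/unmatched in actives vs
background); p-values are Benjamini-Hochberg adjusted, and fragments
significant at the chosen level are reported ranked by descending PFI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .molgraph import Fragment, MolecularGraph, subgraph_exists


class PrivilegedError(ValueError):
    pass


def pfi(f_i: int, a_i: int, T: int) -> float:
    """Privileged fragment index f_i * a_i / T.

    ``f_i``: molecules containing the fragment, ``a_i``: active
    molecules containing it, ``T``: library size.
    """
    if not (0 <= a_i <= f_i <= T) or T <= 0:
        raise PrivilegedError(f"require 0 <= a <= f <= T, T > 0; got {a_i},{f_i},{T}")
    return f_i * a_i / T


def fisher_one_tailed(A: int, B: int, C: int, D: int) -> float:
    """One-sided (enrichment) Fisher exact p for the table [[A, B], [C, D]].

    Sum of hypergeometric probabilities over all tables with the
    observed margins and a >= A.  Computed from the hypergeometric
    survival function.
    """
    for v in (A, B, C, D):
        if v < 0 or int(v) != v:
            raise PrivilegedError("counts must be nonnegative integers")
    N = A + B + C + D
    if N == 0:
        raise PrivilegedError("all-zero table")
    # a ~ Hypergeom(N, row1 = A+B, col1 = A+C); p = P(a >= A)
    return float(hypergeom.sf(A - 1, N, A + B, A + C))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise PrivilegedError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


@dataclass
class PrivilegedFragmentReport:
    fragment: Fragment
    f_i: int
    a_i: int
    T: int
    pfi: float
    p_value: float
    q_value: float
    active_hit_ids: list[str]

    def as_dict(self) -> dict:
        return {
            "canonical_key": self.fragment.canonical_key,
            "f_i": self.f_i,
            "a_i": self.a_i,
            "T": self.T,
            "pfi": self.pfi,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "active_hit_ids": self.active_hit_ids,
        }


def elect_privileged(
    fragments: Sequence[Fragment],
    focused_library: Sequence[MolecularGraph],
    activity_labels: Mapping[str, int] | Sequence[int],
    background_counts: Mapping[str, tuple[int, int]],
    alpha: float = 0.05,
    gate_on: str = "q",
) -> list[PrivilegedFragmentReport]:
    """Elect privileged fragments of a focused library.

    ``background_counts`` maps fragment canonical keys to (matched,
    unmatched) molecule counts in a background library (the role a large
    general-purpose compound collection plays for real targets; the
    synthetic background here).  Enrichment of each fragment in the
    active molecules against that background is Fisher-tested, adjusted
    for FDR, gated at ``alpha`` (on q-values by default, on raw p with
    ``gate_on="p"``), and ranked by descending PFI with canonical-key
    tie-break.
    """
    if gate_on not in ("q", "p"):
        raise PrivilegedError("gate_on must be 'q' or 'p'")
    if not isinstance(activity_labels, Mapping):
        if len(activity_labels) != len(focused_library):
            raise PrivilegedError("labels misaligned with library")
        activity_labels = {
            m.mol_id: int(lab) for m, lab in zip(focused_library, activity_labels)
        }
    actives = [m for m in focused_library if activity_labels.get(m.mol_id) == 1]
    if not actives:
        raise PrivilegedError("no active molecules in the focused library")
    T = len(focused_library)

    rows = []
    for frag in fragments:
        key = frag.canonical_key
        hits = [m.mol_id for m in focused_library if subgraph_exists(frag, m)]
        active_hits = [mid for mid in hits if activity_labels.get(mid) == 1]
        A = len(active_hits)
        B = len(actives) - A
        if key not in background_counts:
            raise PrivilegedError(f"no background counts for fragment {key}")
        C, D = background_counts[key]
        p = fisher_one_tailed(A, B, C, D)
        score = pfi(len(hits), A, T)
        rows.append((frag, len(hits), A, p, score, active_hits))

    q_values = fdr_adjust([r[3] for r in rows])
    reports = [
        PrivilegedFragmentReport(
            fragment=frag,
            f_i=f,
            a_i=a,
            T=T,
            pfi=score,
            p_value=p,
            q_value=float(q),
            active_hit_ids=sorted(hits),
        )
        for (frag, f, a, p, score, hits), q in zip(rows, q_values)
    ]
    gate = (lambda r: r.q_value < alpha) if gate_on == "q" else (lambda r: r.p_value < alpha)
    elected = [r for r in reports if gate(r)]
    elected.sort(key=lambda r: (-r.pfi, r.fragment.canonical_key))
    return elected


def background_presence_counts(
    fragments: Sequence[Fragment], background_library: Sequence[MolecularGraph]
) -> dict[str, tuple[int, int]]:
    """(matched, unmatched) molecule counts per fragment in a background."""
    n = len(background_library)
    out = {}
    for frag in fragments:
        c = sum(1 for m in background_library if subgraph_exists(frag, m))
        out[frag.canonical_key] = (c, n - c)
    return out


def write_report(
    reports: Sequence[PrivilegedFragmentReport],
    path: str | Path,
    renderer=None,
) -> None:
    """TSV + JSON privileged-fragment report."""
    path = Path(path)
    render = renderer or (lambda f: f.canonical_key)
    with open(path.with_suffix(".tsv"), "w") as fh:
        fh.write("fragment\tf_i\ta_i\tT\tpfi\tp_value\tq_value\tactive_hits\n")
        for r in reports:
            fh.write(
                f"{render(r.fragment)}\t{r.f_i}\t{r.a_i}\t{r.T}\t{r.pfi:.6g}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{','.join(r.active_hit_ids)}\n"
            )
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump([r.as_dict() for r in reports], fh, indent=1)
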