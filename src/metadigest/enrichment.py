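"""Over-representation analysis (ORA) of a metabolite list against a GMT
set library, via the hypergeometric upper tail with Benjamini-Hochberg FDR.

Given a query list of n metabolites drawn from a background universe of N,
a set containing b background members, and a = |query ∩ set|, the raw
p-value is P(X >= a) for X ~ Hypergeom(N, b, n): the chance that a random
n-subset of the background hits the set at least a times. Sets passing the
FDR cutoff (default 0.05) are the pathways over-represented among the
metabolites associated with digestive efficiency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("metadigest")


def _normalize_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    key = " ".join(name.split()).casefold()
    if synonyms:
        key = synonyms.get(key, key)
    return key


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values,
    q_(i) = min_{j>=i} (p_(j) * m / j) capped at 1, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    name: str
    description: str
    a: int                     # query metabolites in the set ("a" in reports)
    b: int                     # set size within the background ("b")
    n: int                     # query size
    N: int                     # background size
    p_value: float
    fdr_p: float = float("nan")
    matched: list[str] = field(default_factory=list)
    untestable: bool = False   # b < 2 in background

    @property
    def match(self) -> str:
        """The conventional "a/b" match string."""
        return f"{self.a}/{self.b}"


def ora(query: Iterable[str], library: Mapping[str, Mapping],
        background: Iterable[str] | None = None,
        synonyms: Mapping[str, str] | None = None) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a metabolite list in each
    library set.

    Name matching is case-insensitive and whitespace-trimmed, with an
    optional synonym table; no fuzzy matching. The background universe
    defaults to the union of all library members. Query metabolites absent
    from the background are dropped with a warning (and are visible as the
    difference between the supplied and effective query sizes). Sets with
    no background member are skipped; sets with b < 2 are reported but
    flagged untestable. Results are sorted by raw p-value (ties by name)."""
    syn = {_normalize_name(k): _normalize_name(v)
           for k, v in (synonyms or {}).items()} or None
    sets_norm = {
        name: {_normalize_name(m, syn) for m in entry["members"]}
        for name, entry in library.items()}
    if not sets_norm:
        raise ValueError("empty set library")
    if background is None:
        bg = set().union(*sets_norm.values())
    else:
        bg = {_normalize_name(m, syn) for m in background}
    q_norm: dict[str, str] = {}
    for m in query:
        q_norm.setdefault(_normalize_name(m, syn), m)
    dropped = sorted(k for k in q_norm if k not in bg)
    if dropped:
        warnings.warn(f"{len(dropped)} query metabolite(s) absent from the "
                      f"background and dropped: {dropped[:5]}", stacklevel=2)
    q = {k for k in q_norm if k in bg}
    N, n = len(bg), len(q)

    results: list[EnrichmentResult] = []
    for name, members in sets_norm.items():
        members_bg = members & bg
        b = len(members_bg)
        if b == 0:
            continue
        hits = sorted(q & members_bg)
        a = len(hits)
        p = float(hypergeom.sf(a - 1, N, b, n))
        results.append(EnrichmentResult(
            name=name, description=str(library[name].get("description", "")),
            a=a, b=b, n=n, N=N, p_value=min(p, 1.0),
            matched=[q_norm[h] for h in hits], untestable=b < 2))
    if results:
        adj = bh_fdr([r.p_value for r in results])
        for r, fp in zip(results, adj):
            r.fdr_p = float(fp)
    results.sort(key=lambda r: (r.p_value, r.name))
    return results


def results_table(results: Sequence[EnrichmentResult],
                  fdr_cutoff: float | None = None) -> pd.DataFrame:
    """Tabulate ORA results (columns set, a, b, match, p, fdr_p,
    metabolites); optionally keep only sets below an FDR cutoff."""
    rows = [{
        "set": r.name, "a": r.a, "b": r.b, "match": r.match,
        "p": r.p_value, "fdr_p": r.fdr_p,
        "metabolites": "; ".join(r.matched), "untestable": r.untestable,
    } for r in results]
    df = pd.DataFrame(rows, columns=["set", "a", "b", "match", "p", "fdr_p",
                                     "metabolites", "untestable"])
    if fdr_cutoff is not None:
        df = df[df["fdr_p"] < fdr_cutoff]
    return df.reset_index(drop=True)


def write_results(results: Sequence[EnrichmentResult], path: str | Path,
                  fdr_cutoff: float | None = None) -> None:
    results_table(results, fdr_cutoff).to_csv(path, sep="\t", index=False,
                                              float_format="%.6g")
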