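"""Pairwise community comparison from cluster or genus composition.

Three complementary coefficients are computed for every sample pair:

- Jaccard similarity of the supports (which taxa are present),
- Pearson correlation of relative abundances, and
- the Yue-Clayton theta, an abundance-weighted similarity
  theta = sum(p q) / (sum(p^2) + sum(q^2) - sum(p q)),
  which is 1 iff the two profiles are identical and 0 for disjoint
  supports.

Only confident assignments (top-hit identity >= 94 %) enter a
comparison.  Undefined cases (empty profiles, zero variance) are
reported as NaN and flagged, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiler import DEFAULT_GENUS_IDENTITY, GenusProfile

Profile = Mapping[str, float]


def restrict_to_confident(
    profile: GenusProfile, min_identity: float = DEFAULT_GENUS_IDENTITY
) -> GenusProfile:
    """Drop assignments below the confidence threshold before comparison."""
    kept = [a for a in profile.assignments if a.identity >= min_identity]
    dropped = [a.read_id for a in profile.assignments
               if a.identity < min_identity]
    return GenusProfile(
        profile.sample_id,
        kept,
        list(profile.unassigned_ids) + dropped,
        normalized=profile.normalized,
    )


def _support(p: Profile) -> set[str]:
    return {k for k, v in p.items() if v > 0}


def jaccard(a: Profile, b: Profile) -> float:
    """|support(a) & support(b)| / |support(a) | support(b)|; NaN when
    both supports are empty."""
    sa, sb = _support(a), _support(b)
    union = sa | sb
    if not union:
        return float("nan")
    return len(sa & sb) / len(union)


def _aligned_vectors(a: Profile, b: Profile) -> tuple[np.ndarray, np.ndarray]:
    labels = sorted(_support(a) | _support(b))
    va = np.array([a.get(l, 0.0) for l in labels])
    vb = np.array([b.get(l, 0.0) for l in labels])
    return va, vb


def pearson(a: Profile, b: Profile) -> float:
    """Product-moment correlation of abundances on the label union; NaN
    when either vector has zero variance (including empty profiles)."""
    va, vb = _aligned_vectors(a, b)
    if va.size < 2 or va.std() == 0.0 or vb.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def yue_clayton_theta(a: Profile, b: Profile) -> float:
    """Yue-Clayton theta on relative abundances; NaN when both profiles
    are empty."""
    va, vb = _aligned_vectors(a, b)
    if va.size == 0:
        return float("nan")
    cross = float(va @ vb)
    denom = float(va @ va) + float(vb @ vb) - cross
    if denom == 0.0:
        return float("nan")
    return cross / denom


@dataclass
class ComparisonResult:
    """Symmetric similarity matrices over a sample set."""

    sample_ids: list[str]
    jaccard: pd.DataFrame
    pearson: pd.DataFrame
    theta: pd.DataFrame
    undefined_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for metric, mat in (
            ("jaccard", self.jaccard),
            ("pearson", self.pearson),
            ("theta", self.theta),
        ):
            for i, sa in enumerate(self.sample_ids):
                for sb in self.sample_ids[i + 1 :]:
                    rows.append((sa, sb, metric, mat.loc[sa, sb]))
        return pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "metric", "value"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def compare_samples(profiles: Mapping[str, Profile]) -> ComparisonResult:
    """All three coefficients for all sample pairs.

    Diagonals are 1 by definition; undefined pairs are NaN and listed in
    ``undefined_pairs`` as (sample_a, sample_b, metric).
    """
    ids = list(profiles)
    if len(ids) < 2:
        raise ValueError("need at least two profiles to compare")
    mats = {
        m: pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for m in ("jaccard", "pearson", "theta")
    }
    undefined: list[tuple[str, str, str]] = []
    fns = {"jaccard": jaccard, "pearson": pearson, "theta": yue_clayton_theta}
    for i, sa in enumerate(ids):
        for sb in ids[i + 1 :]:
            for metric, fn in fns.items():
                v = fn(profiles[sa], profiles[sb])
                mats[metric].loc[sa, sb] = v
                mats[metric].loc[sb, sa] = v
                if math.isnan(v):
                    undefined.append((sa, sb, metric))
    return ComparisonResult(
        ids, mats["jaccard"], mats["pearson"], mats["theta"], undefined
    )


def profiles_from_tsvs(paths: Sequence[str | Path]) -> dict[str, Profile]:
    """Load genus-composition TSVs keyed by file stem."""
    out: dict[str, Profile] = {}
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        out[path.stem] = dict(
            zip(df["genus"], df["relative_abundance"])
        )
    return out
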