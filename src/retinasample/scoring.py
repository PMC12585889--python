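"""Identity scoring: embeddings, match/non-match pairs, similarity, AUC.

A probe (the composite retinal image from one learning trial) is compared with
gallery images: the same identity showing the other facial expression (match)
and a demographically matched different identity, also in a different
expression (non-match) — one of each per probe, so match and non-match counts
are balanced by construction. Comparison is the Euclidean distance between
embedding vectors, min-max normalized per backend over the whole experiment
and inverted into a similarity in [0, 1]. Discriminability per condition cell
is the area under the ROC curve, computed exactly as the tie-aware
Mann-Whitney probability P(sim_match > sim_nonmatch) + 0.5 P(tie).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.transform import resize

SCORING_SIZE = 224


@dataclass(frozen=True)
class ConditionCell:
    backend: str
    source_label: str
    spotlight_pct: int
    auc: float
    n_match: int
    n_nonmatch: int


class GridStatsBackend:
    """Deterministic hand-crafted embedding: grid-cell image statistics.

    The image is resized to 224x224 and split into a grid x grid lattice; each
    cell contributes its mean, standard deviation and four oriented gradient
    energies (horizontal, vertical and both diagonals), giving a
    grid*grid*6-dimensional descriptor. Sensitive to local texture (hence to
    the synthetic identity patches) and to small translations.
    """

    def __init__(self, grid: int = 8):
        if SCORING_SIZE % grid:
            raise ValueError(f"grid must divide {SCORING_SIZE}")
        self.grid = grid
        self.name = f"gridstats{grid}"
        self.embedding_dim = grid * grid * 6

    def embed(self, pixels: np.ndarray) -> np.ndarray:
        img = np.asarray(pixels, dtype=float)
        if not np.isfinite(img).all():
            raise ValueError("image contains non-finite pixels")
        if img.shape != (SCORING_SIZE, SCORING_SIZE):
            img = resize(img, (SCORING_SIZE, SCORING_SIZE), anti_aliasing=True)
        gy, gx = np.gradient(img)
        d1 = (gx + gy) / np.sqrt(2.0)
        d2 = (gx - gy) / np.sqrt(2.0)
        g = self.grid
        feats = []
        for chan, stat in ((img, "mean"), (img, "sd"), (np.abs(gx), "mean"),
                           (np.abs(gy), "mean"), (np.abs(d1), "mean"),
                           (np.abs(d2), "mean")):
            cells = chan.reshape(g, SCORING_SIZE // g, g, SCORING_SIZE // g)
            if stat == "mean":
                feats.append(cells.mean(axis=(1, 3)))
            else:
                feats.append(cells.std(axis=(1, 3)))
        return np.concatenate([f.ravel() for f in feats])


def default_backends() -> list[GridStatsBackend]:
    """Backend ensemble standing in for a set of recognition networks."""
    return [GridStatsBackend(7), GridStatsBackend(8), GridStatsBackend(14)]


def build_pairs(probes: list[dict], identities: list, seed: int = 0) -> list[dict]:
    """Attach one match and one non-match gallery to every probe.

    ``probes`` are dicts with at least ``identity_id`` and ``expression`` (the
    expression shown at learning). The match gallery is the same identity in
    the other expression; the non-match gallery is a demographic peer (same
    gender, ethnicity and age band), also in the other expression, chosen by a
    seeded shuffle when several peers exist.
    """
    demo = {i.identity_id: tuple(sorted(i.demographics.items())) for i in identities}
    peers: dict[str, list[str]] = {}
    for iid, d in demo.items():
        peers[iid] = sorted(j for j, dj in demo.items() if dj == d and j != iid)
    rng = np.random.default_rng(seed)
    pairs = []
    for probe in probes:
        iid, expr = probe["identity_id"], probe["expression"]
        if iid not in demo:
            raise ValueError(f"unknown identity {iid}")
        if not peers[iid]:
            raise ValueError(f"identity {iid} has no demographic peer")
        other = "happy" if expr == "neutral" else "neutral"
        partner = peers[iid][rng.integers(len(peers[iid]))]
        pairs.append({**probe, "is_match": True,
                      "gallery_identity": iid, "gallery_expression": other})
        pairs.append({**probe, "is_match": False,
                      "gallery_identity": partner, "gallery_expression": other})
    return pairs


def normalized_similarity(distances: np.ndarray) -> np.ndarray:
    """Invert min-max normalized distances into similarities in [0, 1].

    The span is taken over the given distance set (one backend's full
    experiment). A degenerate backend with zero span yields 0.5 everywhere.
    """
    d = np.asarray(distances, dtype=float)
    dmin, dmax = float(d.min()), float(d.max())
    if dmax == dmin:
        warnings.warn("degenerate backend: all pairwise distances equal",
                      stacklevel=2)
        return np.full(d.shape, 0.5)
    return np.clip(1.0 - (d - dmin) / (dmax - dmin), 0.0, 1.0)


def correctness(similarity: np.ndarray, is_match: np.ndarray) -> np.ndarray:
    """Similarity on match trials, reversed on non-match trials."""
    sim = np.asarray(similarity, dtype=float)
    return np.where(np.asarray(is_match, bool), sim, 1.0 - sim)


def mann_whitney_auc(match_scores, nonmatch_scores) -> float:
    """Exact tie-aware AUC: P(match > nonmatch) + 0.5 P(match == nonmatch)."""
    m = np.asarray(match_scores, dtype=float)
    nm = np.asarray(nonmatch_scores, dtype=float)
    if len(m) == 0 or len(nm) == 0:
        raise ValueError("need at least one match and one non-match score")
    ranks = rankdata(np.concatenate([m, nm]))
    u = ranks[:len(m)].sum() - len(m) * (len(m) + 1) / 2.0
    return float(u / (len(m) * len(nm)))


def auc_cell(scores: pd.DataFrame, backend: str, source_label: str,
             spotlight_pct: int) -> ConditionCell:
    """AUC for one (backend, source, spotlight) cell of a pair-score table."""
    m = scores.loc[scores["is_match"], "similarity"].to_numpy()
    nm = scores.loc[~scores["is_match"], "similarity"].to_numpy()
    return ConditionCell(backend=backend, source_label=source_label,
                         spotlight_pct=spotlight_pct,
                         auc=mann_whitney_auc(m, nm),
                         n_match=len(m), n_nonmatch=len(nm))


def auc_table(scores: pd.DataFrame) -> pd.DataFrame:
    """One AUC row per (backend, source, spotlight) cell."""
    rows = []
    for (be, src, pct), g in scores.groupby(["backend", "source_label",
                                             "spotlight_pct"]):
        cell = auc_cell(g, be, src, int(pct))
        rows.append({"backend": be, "source_label": src, "spotlight_pct": int(pct),
                     "auc": cell.auc, "n_match": cell.n_match,
                     "n_nonmatch": cell.n_nonmatch})
    return pd.DataFrame(rows)
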