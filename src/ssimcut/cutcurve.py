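"""SSIM cut curve: separating dissimilar early layers from similar deep ones.

For a model with n convolutional layers and pairwise visualization
similarities s_ij, the cut value at position k is the mean similarity across
the cut {L_1..L_k} | {L_k+1..L_n}:

    C_k = 1/(k (n-k)) * sum_{i<=k} sum_{j>k} s_ij ,   k = 1..n-1

Equivalently, with row sums M_i = sum_j s_ij,

    C_k = 1/(k (n-k)) * ( sum_{i<=k} M_i - sum_{i<=k} sum_{j<=k} s_ij ).

C_k as a function of k is the *cut curve*. A curve that rises and then goes
flat says the deeper layers learn features that look alike — extra depth buys
nothing; a curve that keeps rising says every layer still adds diverse
features. The elbow of the curve is therefore a depth recommendation.

Two elbow readings are implemented and both are always reported:

* ``chord_distance`` — the k maximizing the perpendicular distance from
  (k, C_k) to the chord joining the curve's endpoints (the classic elbow
  criterion; the absolute distance is used so that V-shaped curves, whose
  informative point lies *below* the chord, are handled too);
* ``delta_threshold`` — the smallest k whose forward difference
  dC_k = C_{k+1} - C_k falls below a fraction tau of the largest difference.

If no difference ever falls below the threshold the curve is *still rising*
(the model may need more depth); a constant curve is *degenerate*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gbp import all_layer_visualizations
from .similarity import SSIMMatrix, SSIMParams, pairwise_ssim_matrix

__all__ = [
    "CutCurve", "CutDifference", "RowSums", "DepthRecommendation",
    "cut_value", "cut_value_rowsum", "row_sums", "cut_curve",
    "cut_difference", "flat_condition_residual", "mean_cut_curve",
    "recommend_depth", "preferred_candidate", "analyze_model",
    "SSIMCutAnalysis", "SSIMCutResults",
]

DEGENERATE_TOL = 1e-9
DEFAULT_TAU = 0.1


@dataclass
class CutCurve:
    values: np.ndarray  # C_1 .. C_{n-1}
    layer_count: int
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.layer_count - 1:
            raise ValueError("cut curve length must be layer_count - 1")


@dataclass
class CutDifference:
    values: np.ndarray  # dC_1 .. dC_{n-2}


@dataclass
class RowSums:
    values: np.ndarray  # M_1 .. M_n, diagonal included


@dataclass
class DepthRecommendation:
    k_star: int | None
    method: str
    verdict: str  # {"depth_sufficient", "still_rising", "degenerate"}
    diagnostics: dict = field(default_factory=dict)


def _values(S) -> np.ndarray:
    return S.values if isinstance(S, SSIMMatrix) else np.asarray(S)


def _check_k(n: int, k: int, upper: int) -> None:
    if not 1 <= k <= upper:
        raise IndexError(f"k={k} out of range 1..{upper} for n={n}")


def cut_value(S, k: int) -> float:
    """C_k: mean pairwise similarity across the cut at position k."""
    v = _values(S)
    n = len(v)
    _check_k(n, k, n - 1)
    return float(v[:k, k:].sum() / (k * (n - k)))


def row_sums(S) -> RowSums:
    return RowSums(_values(S).sum(axis=1))


def cut_value_rowsum(S, k: int, M: RowSums | None = None) -> float:
    """C_k via the row-sum rewriting; identical to :func:`cut_value`."""
    v = _values(S)
    n = len(v)
    _check_k(n, k, n - 1)
    M = M or row_sums(v)
    m = np.asarray(M.values)
    if len(m) != n:
        raise ValueError("row sums inconsistent with matrix size")
    return float((m[:k].sum() - v[:k, :k].sum()) / (k * (n - k)))


def cut_curve(S, provenance: list[str] | None = None) -> CutCurve:
    v = _values(S)
    n = len(v)
    if n < 2:
        raise ValueError("cut curve needs >= 2 layers")
    vals = np.array([cut_value(v, k) for k in range(1, n)])
    prov = provenance or (
        [S.image_id] if isinstance(S, SSIMMatrix) and S.image_id else []
    )
    return CutCurve(vals, n, prov)


def cut_difference(curve: CutCurve) -> CutDifference:
    """Forward differences dC_k = C_{k+1} - C_k, k = 1..n-2."""
    if curve.layer_count < 3:
        raise ValueError("cut difference needs >= 3 layers")
    return CutDifference(np.diff(curve.values))


def flat_condition_residual(S, k: int) -> float:
    """Balance diagnostic r = M_{k+1} - 2 * sum_{i<=k+1} s_{i,k+1}.

    Near-zero r means layer k+1 is as similar to the layers before it as to
    the layers after it — the regime where the cut curve is locally flat.
    Approximate (the derivation drops the prefactor's variation); exposed as
    a diagnostic, never asserted.
    """
    v = _values(S)
    n = len(v)
    _check_k(n, k, n - 2)
    col = v[:, k]  # similarities of layer k+1 (0-based column k)
    return float(col.sum() - 2.0 * col[: k + 1].sum())


def mean_cut_curve(curves: list[CutCurve]) -> CutCurve:
    """Pointwise mean of cut curves (e.g., one curve per sampled image)."""
    if not curves:
        raise ValueError("no curves to average")
    lengths = {len(c.values) for c in curves}
    if len(lengths) > 1:
        raise ValueError(f"mixed curve lengths: {sorted(lengths)}")
    vals = np.mean([c.values for c in curves], axis=0)
    prov = [p for c in curves for p in c.provenance]
    return CutCurve(vals, curves[0].layer_count, prov)


def _chord_distances(values: np.ndarray) -> np.ndarray:
    """|perpendicular distance| of each curve point to the endpoint chord."""
    x = np.arange(1, len(values) + 1, dtype=float)
    x0, y0, x1, y1 = x[0], values[0], x[-1], values[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    return np.abs(dy * (x - x0) - dx * (values - y0)) / norm


def recommend_depth(curve: CutCurve, method: str = "chord_distance",
                    tau: float = DEFAULT_TAU) -> DepthRecommendation:
    """Elbow-based depth recommendation from a cut curve.

    Both criteria are always evaluated and reported in ``diagnostics``;
    ``method`` selects which one supplies ``k_star``.
    """
    vals = curve.values
    n = curve.layer_count
    if n < 4:
        raise ValueError("depth recommendation needs >= 4 layers")
    if method not in ("chord_distance", "delta_threshold"):
        raise ValueError(f"unknown method {method!r}")

    diagnostics: dict = {"tau": tau}
    if vals.max() - vals.min() < DEGENERATE_TOL:
        return DepthRecommendation(None, method, "degenerate", diagnostics)

    dist = _chord_distances(vals)
    k_chord = int(np.argmax(dist)) + 1  # argmax breaks ties toward smaller k
    diagnostics["chord_distance"] = {"k": k_chord, "distances": dist.tolist()}

    delta = np.diff(vals)
    dmax = float(delta.max())
    below = np.flatnonzero(delta < tau * dmax)
    k_delta = int(below[0]) + 1 if len(below) else None
    diagnostics["delta_threshold"] = {
        "k": k_delta,
        "delta": delta.tolist(),
        "threshold": tau * dmax,
    }

    if k_delta is None:
        # every difference stays large: the curve is still rising
        return DepthRecommendation(None, method, "still_rising", diagnostics)

    k_star = k_chord if method == "chord_distance" else k_delta
    return DepthRecommendation(k_star, method, "depth_sufficient", diagnostics)


def preferred_candidate(k_star: int, candidate_depths: list[int]) -> int | None:
    """Smallest candidate depth that can realize a recommendation k_star."""
    ok = [d for d in candidate_depths if d >= k_star]
    return min(ok) if ok else None


# ---------------------------------------------------------------------------
# Model/Results layer
# ---------------------------------------------------------------------------

class SSIMCutAnalysis:
    """Cut-curve analysis of one CNN on a set of images.

    Parameters
    ----------
    model : Network
        A model exposing ordered included conv layers (>= 2; >= 4 for a depth
        recommendation).
    images : array or list of (H, W, 3) arrays
        Images to analyze; curves are averaged over them.
    labels : optional array of class ids
        Enables per-class mean curves.
    ssim_params, seed_mode
        Passed through to the similarity and GBP stages.
    image_ids : optional provenance strings, one per image.
    """

    def __init__(self, model, images, labels=None,
                 ssim_params: SSIMParams | None = None,
                 seed_mode: str = "ones", image_ids: list[str] | None = None):
        self.model = model
        self.images = list(images)
        if not self.images:
            raise ValueError("need at least one image")
        self.labels = None if labels is None else np.asarray(labels)
        self.ssim_params = ssim_params or SSIMParams()
        self.seed_mode = seed_mode
        self.image_ids = image_ids or [f"image_{i}" for i in range(len(self.images))]

    @classmethod
    def from_dataset(cls, model, dataset, images_per_class: int = 1,
                     seed: int = 0, partition: str = "test", **kwargs):
        """Sample ``images_per_class`` random images per class from a split
        (default: one test image per class) — the usual sampling protocol."""
        rng = np.random.default_rng(seed)
        idx = np.asarray(dataset.split[partition])
        chosen: list[int] = []
        for c in np.unique(dataset.labels[idx]):
            pool = idx[dataset.labels[idx] == c]
            take = rng.choice(pool, size=min(images_per_class, len(pool)),
                              replace=False)
            chosen.extend(int(i) for i in take)
        ids = [dataset.filenames[i] if dataset.filenames else f"image_{i}"
               for i in chosen]
        return cls(model, [dataset.images[i] for i in chosen],
                   labels=dataset.labels[chosen], image_ids=ids, **kwargs)

    def fit(self, method: str = "chord_distance", tau: float = DEFAULT_TAU,
            validate: bool = True) -> "SSIMCutResults":
        matrices, curves = [], []
        for img, img_id in zip(self.images, self.image_ids):
            try:
                vis = all_layer_visualizations(self.model, img, self.seed_mode)
                S = pairwise_ssim_matrix(vis, self.ssim_params, image_id=img_id)
                if validate:
                    S.validate(atol=1e-9)
                matrices.append(S)
                curves.append(cut_curve(S))
            except Exception as exc:
                raise RuntimeError(f"analysis failed on image {img_id!r}") from exc

        mean_curve = mean_cut_curve(curves)
        per_class: dict[int, CutCurve] = {}
        if self.labels is not None:
            for c in np.unique(self.labels):
                sel = [cv for cv, lb in zip(curves, self.labels) if lb == c]
                per_class[int(c)] = mean_cut_curve(sel)

        n = mean_curve.layer_count
        delta = cut_difference(mean_curve) if n >= 3 else None
        rec = recommend_depth(mean_curve, method, tau) if n >= 4 else None
        return SSIMCutResults(self, matrices, curves, mean_curve, per_class,
                              delta, rec, {"method": method, "tau": tau,
                                           "seed_mode": self.seed_mode})


class SSIMCutResults:
    """Fitted cut-curve analysis: matrices, curves, and the recommendation."""

    def __init__(self, analysis, matrices, per_image_curves, mean_curve,
                 per_class_curves, delta, recommendation, config):
        self.analysis = analysis
        self.matrices: list[SSIMMatrix] = matrices
        self.per_image_curves: list[CutCurve] = per_image_curves
        self.curve: CutCurve = mean_curve
        self.per_class_curves: dict[int, CutCurve] = per_class_curves
        self.delta: CutDifference | None = delta
        self.recommendation: DepthRecommendation | None = recommendation
        self.config = config

    @property
    def k_star(self) -> int | None:
        return self.recommendation.k_star if self.recommendation else None

    @property
    def verdict(self) -> str | None:
        return self.recommendation.verdict if self.recommendation else None

    def to_dict(self) -> dict:
        rec = self.recommendation
        return {
            "layer_count": self.curve.layer_count,
            "curve": self.curve.values.tolist(),
            "delta": self.delta.values.tolist() if self.delta else None,
            "per_class_curves": {str(c): cv.values.tolist()
                                 for c, cv in self.per_class_curves.items()},
            "k_star": rec.k_star if rec else None,
            "verdict": rec.verdict if rec else None,
            "diagnostics": rec.diagnostics if rec else None,
            "provenance": self.curve.provenance,
            "config": self.config,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    def save_curve_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("k,cut_value\n")
            for k, v in enumerate(self.curve.values, start=1):
                fh.write(f"{k},{v!r}\n")

    def plot(self, ax=None):
        """Line plot of the mean cut curve and its differences (cosmetic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(1, len(self.curve.values) + 1)
        ax.plot(k, self.curve.values, marker="o", label="cut value $C_k$")
        if self.delta is not None:
            ax.plot(k[:-1] + 0.5, self.delta.values, marker=".",
                    label=r"difference $\Delta C_k$")
        ax.set_xlabel("cut position k (layer)")
        ax.set_ylabel("SSIM cut value")
        ax.legend()
        return ax

    def summary(self) -> str:
        n = self.curve.layer_count
        lines = [
            "SSIM cut-curve analysis",
            "=" * 47,
            f"conv layers (n):        {n}",
            f"images averaged:        {len(self.per_image_curves)}",
            f"SSIM channel mode:      {self.analysis.ssim_params.channel_mode}",
            f"GBP seed mode:          {self.config['seed_mode']}",
            "-" * 47,
            "  k      C_k     dC_k",
        ]
        for k in range(1, n):
            d = (f"{self.delta.values[k - 1]: .4f}"
                 if self.delta is not None and k <= n - 2 else "      ")
            lines.append(f"{k:3d}   {self.curve.values[k - 1]: .4f}  {d}")
        lines.append("-" * 47)
        if self.recommendation is None:
            lines.append("recommendation: n/a (model too shallow)")
        else:
            r = self.recommendation
            lines.append(f"verdict:  {r.verdict}")
            if r.k_star is not None:
                lines.append(f"recommended cut k*: {r.k_star}  (method: {r.method})")
            kd = r.diagnostics.get("delta_threshold", {}).get("k")
            kc = r.diagnostics.get("chord_distance", {}).get("k")
            lines.append(f"elbow by chord distance: {kc}; by delta threshold: {kd}")
        return "\n".join(lines)


def analyze_model(model, images, labels=None, ssim_params=None,
                  seed_mode: str = "ones", method: str = "chord_distance",
                  tau: float = DEFAULT_TAU, image_ids=None) -> SSIMCutResults:
    """Functional one-shot wrapper around :class:`SSIMCutAnalysis`."""
    return SSIMCutAnalysis(model, images, labels, ssim_params, seed_mode,
                           image_ids).fit(method=method, tau=tau)
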