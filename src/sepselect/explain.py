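"""Per-patient attributions and cohort-level feature rankings.

Integrated gradients attribute a model's output to its inputs by
integrating the gradient along the straight line from a baseline input x'
to the actual input x:

    phi_i = (x_i - x'_i) * integral_0^1 df(x' + a (x - x')) / dx_i da

approximated here with a right-Riemann sum over ``steps`` interpolation
points. The method satisfies completeness — the attributions sum to
f(x) - f(x') as the step count grows — and is exact on linear models for
any step count. The default baseline is the all-zero vector in
standardized feature space, i.e. the cohort-mean patient.

The Actor's selection probabilities give a complementary, model-native
explanation: averaging them over a cohort and sorting yields the ranking
of features the selector relies on most.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor


@dataclass
class Attribution:
    phi: np.ndarray
    x: np.ndarray
    x_prime: np.ndarray
    steps: int
    f_x: float
    f_xprime: float

    @property
    def completeness_gap(self) -> float:
        return abs(float(self.phi.sum()) - (self.f_x - self.f_xprime))


@dataclass
class FeatureRanking:
    feature_names: list[str]
    mean_probs: np.ndarray

    def to_dict(self) -> dict:
        return {"feature_names": self.feature_names,
                "mean_probs": [float(v) for v in self.mean_probs]}


def integrated_gradients(model_fn, x: np.ndarray,
                         x_prime: np.ndarray | None = None,
                         steps: int = 128, *,
                         method: str = "right") -> Attribution:
    """Integrated-gradients attribution of a scalar-output model.

    ``model_fn`` maps a batch Tensor (m, d) to a Tensor of m outputs and
    must be differentiable; all interpolants are evaluated in one batched
    forward/backward pass. ``method`` selects the Riemann rule: ``right``
    (default) or ``trapezoid``.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_prime = np.zeros_like(x) if x_prime is None else \
        np.asarray(x_prime, dtype=float).ravel()
    if x.shape != x_prime.shape:
        raise ValueError("x and x_prime must have equal shape")
    if steps < 1:
        raise ValueError("steps must be >= 1")

    if method == "right":
        alphas = np.arange(1, steps + 1) / steps
        weights = np.full(steps, 1.0 / steps)
    elif method == "trapezoid":
        alphas = np.arange(0, steps + 1) / steps
        weights = np.full(steps + 1, 1.0 / steps)
        weights[0] = weights[-1] = 0.5 / steps
    else:
        raise ValueError(f"unknown method {method!r}")

    interp = x_prime[None, :] + alphas[:, None] * (x - x_prime)[None, :]
    t = Tensor(interp, requires_grad=True)
    out = model_fn(t)
    out.sum().backward()
    if t.grad is None or not np.isfinite(t.grad).all():
        bad = 0 if t.grad is None else int(np.argwhere(
            ~np.isfinite(t.grad).all(axis=1)).ravel()[0])
        raise FloatingPointError(
            f"non-finite gradient at interpolation index {bad}")
    avg_grad = (weights[:, None] * t.grad).sum(axis=0)
    phi = (x - x_prime) * avg_grad

    f_x = float(model_fn(Tensor(x[None, :])).data[0])
    f_xp = float(model_fn(Tensor(x_prime[None, :])).data[0])
    return Attribution(phi, x, x_prime, steps, f_x, f_xp)


def rank_selection_probabilities(S_d: np.ndarray,
                                 feature_names: list[str]) -> FeatureRanking:
    """Cohort-mean selection probability per feature, sorted descending.

    Ties are broken alphabetically by feature name.
    """
    S = np.atleast_2d(np.asarray(S_d, dtype=float))
    if S.shape[1] != len(feature_names):
        raise ValueError("feature_names must match the probability columns")
    means = S.mean(axis=0)
    order = sorted(range(len(feature_names)),
                   key=lambda j: (-means[j], feature_names[j]))
    return FeatureRanking([feature_names[j] for j in order], means[order])


def export_explanations(attributions: dict[str, Attribution],
                        masks: dict[str, np.ndarray],
                        feature_names: list[str], out_dir) -> list[Path]:
    """Write one attribution CSV and one heat-map PNG per patient.

    The CSV holds feature name, attribution value and whether the Actor
    selected the feature; the heat map shows the signed attributions.
    Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for pid, att in attributions.items():
        mask = np.asarray(masks.get(pid, np.ones_like(att.phi)))
        csv_path = out_dir / f"{pid}_attribution.csv"
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["feature", "phi", "selected"])
            for name, v, m in zip(feature_names, att.phi, mask):
                w.writerow([name, repr(float(v)), int(m)])
        written.append(csv_path)

        fig, ax = plt.subplots(figsize=(10, 1.8))
        vmax = max(float(np.abs(att.phi).max()), 1e-12)
        im = ax.imshow(att.phi[None, :], aspect="auto", cmap="coolwarm",
                       vmin=-vmax, vmax=vmax)
        ax.set_yticks([])
        ax.set_xticks(range(len(feature_names)))
        ax.set_xticklabels(feature_names, rotation=90, fontsize=6)
        ax.set_title(f"{pid}: integrated-gradients attribution")
        fig.colorbar(im, ax=ax, fraction=0.025)
        png_path = out_dir / f"{pid}_heatmap.png"
        fig.savefig(png_path, bbox_inches="tight", dpi=120)
        plt.close(fig)
        written.append(png_path)
    return written


def read_attribution_csv(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Round-trip reader for :func:`export_explanations` CSVs."""
    names, phi, sel = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["feature"])
            phi.append(float(row["phi"]))
            sel.append(int(row["selected"]))
    return names, np.array(phi), np.array(sel)
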