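"""Two-way admixture ancestry estimation from ancestry-informative markers.

Each individual's genome is modelled as a mixture of two ancestral
populations (here: West African and European). Given a panel of markers
with known ancestral allele frequencies ``pA_m`` and ``pB_m``, the diploid
genotype at marker *m* is Binomial(2, p_m(theta)) with

    p_m(theta) = theta * pA_m + (1 - theta) * pB_m,

where theta is the admixture proportion toward population A. The
log-likelihood is a sum of logs of terms affine in theta, hence concave, and
is maximised on [0, 1] by bounded scalar optimisation with an explicit
boundary check. Missing genotypes are dropped per individual; ancestral
frequencies are treated as known constants, optionally clamped away from
{0, 1} (``clamp_eps``) to guard against markers fixed in one reference
panel.

:class:`AdmixtureModel` / :class:`AdmixtureResults` expose the estimator in
the fit/results idiom: the model wraps a genotype matrix and a panel, and
``fit()`` returns per-individual estimates with a ``summary()`` table and a
case/control balance test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import cohortstats

#: log binomial coefficients log C(2, g) for g = 0, 1, 2
_LOG_COEF = np.log([1.0, 2.0, 1.0])


@dataclass(frozen=True)
class AIMsPanel:
    """Ancestry-informative marker panel with two-population frequencies."""

    marker_ids: tuple[str, ...]
    freq_a: np.ndarray  # allele frequency in ancestral population A
    freq_b: np.ndarray  # allele frequency in ancestral population B

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_a", np.asarray(self.freq_a, dtype=float))
        object.__setattr__(self, "freq_b", np.asarray(self.freq_b, dtype=float))
        if len(self.marker_ids) != self.freq_a.size or self.freq_a.size != self.freq_b.size:
            raise ValueError("marker ids and frequency arrays must align")
        for f in (self.freq_a, self.freq_b):
            if not np.all(np.isfinite(f)) or f.min() < 0 or f.max() > 1:
                raise ValueError("ancestral frequencies must lie in [0, 1]")

    @property
    def n_markers(self) -> int:
        return self.freq_a.size

    @property
    def delta(self) -> float:
        """Mean absolute ancestral allele-frequency difference."""
        return float(np.mean(np.abs(self.freq_a - self.freq_b)))

    def clamped(self, eps: float) -> "AIMsPanel":
        """Panel with frequencies pulled into [eps, 1 - eps]."""
        return AIMsPanel(
            self.marker_ids,
            np.clip(self.freq_a, eps, 1 - eps),
            np.clip(self.freq_b, eps, 1 - eps),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "freq_popA": self.freq_a, "freq_popB": self.freq_b}
        )

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "AIMsPanel":
        t = pd.read_csv(path, sep="\t")
        return cls(
            tuple(t["marker_id"].astype(str)),
            t["freq_popA"].to_numpy(float),
            t["freq_popB"].to_numpy(float),
        )


@dataclass(frozen=True)
class AncestryEstimate:
    """Maximum-likelihood admixture proportion for one individual."""

    theta: float
    loglik: float
    n_markers_used: int
    converged: bool


def admixture_loglik(
    theta: float,
    genotypes: np.ndarray,
    panel: AIMsPanel,
    clamp_eps: float = 0.0,
) -> float:
    """Log-likelihood of theta for one individual's AIMs genotypes.

    Missing genotypes (negative dosage) contribute nothing. With
    ``clamp_eps == 0`` a marker whose mixture frequency is exactly 0 or 1
    contributes ``-inf`` only when the observed genotype is impossible
    under it.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    g = np.asarray(genotypes, dtype=float)
    called = g >= 0
    if not called.any():
        raise ValueError("all markers missing for this individual")
    g = g[called]
    pa, pb = panel.freq_a[called], panel.freq_b[called]
    if clamp_eps > 0:
        pa, pb = np.clip(pa, clamp_eps, 1 - clamp_eps), np.clip(pb, clamp_eps, 1 - clamp_eps)
    p = theta * pa + (1.0 - theta) * pb
    with np.errstate(divide="ignore", invalid="ignore"):
        term = g * np.log(p) + (2.0 - g) * np.log1p(-p)
    # 0 * log(0) is a structural zero, not an impossibility
    term = np.where((g == 0) & (p == 0), 0.0, term)
    term = np.where((g == 2) & (p == 1), 0.0, term)
    return float(np.sum(term + _LOG_COEF[g.astype(int)]))


def estimate_theta(
    genotypes: np.ndarray,
    panel: AIMsPanel,
    tol: float = 1e-6,
    clamp_eps: float = 1e-3,
) -> AncestryEstimate:
    """Maximise the admixture likelihood on [0, 1] for one individual.

    Boundary maxima are legal and reported with ``converged=True``. A panel
    with identical frequencies in both populations at every marker carries
    no ancestry information and is rejected.
    """
    g = np.asarray(genotypes, dtype=float)
    called = g >= 0
    if not called.any():
        raise ValueError("all markers missing for this individual")
    pa = np.clip(panel.freq_a, clamp_eps, 1 - clamp_eps) if clamp_eps > 0 else panel.freq_a
    pb = np.clip(panel.freq_b, clamp_eps, 1 - clamp_eps) if clamp_eps > 0 else panel.freq_b
    if np.max(np.abs(pa[called] - pb[called])) < 1e-12:
        raise ValueError("panel is non-identifiable: pA == pB at every called marker")

    def nll(theta: float) -> float:
        return -admixture_loglik(theta, genotypes, panel, clamp_eps=clamp_eps)

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": tol})
    candidates = [(float(res.x), -res.fun), (0.0, -nll(0.0)), (1.0, -nll(1.0))]
    theta, loglik = max(candidates, key=lambda c: c[1])
    return AncestryEstimate(
        theta=theta,
        loglik=loglik,
        n_markers_used=int(called.sum()),
        converged=bool(res.success),
    )


@dataclass(frozen=True)
class AncestryBalance:
    """Case/control comparison of estimated admixture proportions."""

    case_mean: float
    case_sd: float
    case_n: int
    control_mean: float
    control_sd: float
    control_n: int
    t: float
    df: float
    p: float


def ancestry_balance(
    estimates: list[AncestryEstimate], is_case: np.ndarray
) -> AncestryBalance:
    """Group means +- SD of theta with a two-tailed Welch t-test."""
    thetas = np.array([e.theta for e in estimates])
    is_case = np.asarray(is_case, dtype=bool)
    if thetas.size != is_case.size:
        raise ValueError("estimates and labels must align")
    cases, controls = thetas[is_case], thetas[~is_case]
    if cases.size < 2 or controls.size < 2:
        raise ValueError("each group needs at least two individuals")
    tt = cohortstats.t_test_from_values(cases, controls, equal_var=False)
    return AncestryBalance(
        case_mean=float(cases.mean()),
        case_sd=float(cases.std(ddof=1)),
        case_n=cases.size,
        control_mean=float(controls.mean()),
        control_sd=float(controls.std(ddof=1)),
        control_n=controls.size,
        t=tt.t,
        df=tt.df,
        p=tt.p,
    )


class AdmixtureModel:
    """Two-way admixture model over a cohort's AIMs genotypes.

    Parameters
    ----------
    genotypes : array-like, shape (n_individuals, n_markers)
        Diploid alt-allele dosages aligned to the panel; negative = missing.
    panel : AIMsPanel
    sample_ids, is_case : optional labels carried through to the results.
    """

    def __init__(
        self,
        genotypes: np.ndarray,
        panel: AIMsPanel,
        sample_ids: list[str] | None = None,
        is_case: np.ndarray | None = None,
        clamp_eps: float = 1e-3,
    ) -> None:
        self.genotypes = np.asarray(genotypes)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != panel.n_markers:
            raise ValueError("genotype matrix must be (n_individuals, n_markers)")
        self.panel = panel
        self.sample_ids = sample_ids or [f"ind{i}" for i in range(self.genotypes.shape[0])]
        self.is_case = None if is_case is None else np.asarray(is_case, dtype=bool)
        self.clamp_eps = clamp_eps

    @classmethod
    def from_files(
        cls,
        dosage_tsv: str | os.PathLike,
        panel_tsv: str | os.PathLike,
        phenotype_tsv: str | os.PathLike | None = None,
    ) -> "AdmixtureModel":
        """Build from a samples x markers dosage TSV and a panel TSV."""
        from .cohort import read_phenotypes

        panel = AIMsPanel.read(panel_tsv)
        dosages = pd.read_csv(dosage_tsv, sep="\t", index_col=0)
        dosages = dosages[list(panel.marker_ids)]
        is_case = None
        if phenotype_tsv is not None:
            sheet = read_phenotypes(phenotype_tsv)
            status = dict(zip(sheet["sample_id"], sheet["status"]))
            missing = [s for s in dosages.index if s not in status]
            if missing:
                raise ValueError(f"samples absent from phenotype sheet: {missing}")
            is_case = np.array([status[s] == "case" for s in dosages.index])
        return cls(
            dosages.to_numpy(),
            panel,
            sample_ids=list(dosages.index.astype(str)),
            is_case=is_case,
        )

    def fit(self, tol: float = 1e-6) -> "AdmixtureResults":
        estimates = [
            estimate_theta(self.genotypes[i], self.panel, tol=tol, clamp_eps=self.clamp_eps)
            for i in range(self.genotypes.shape[0])
        ]
        return AdmixtureResults(self, estimates)


class AdmixtureResults:
    """Per-individual admixture estimates with summary and balance views."""

    def __init__(self, model: AdmixtureModel, estimates: list[AncestryEstimate]) -> None:
        self.model = model
        self.estimates = estimates

    @property
    def thetas(self) -> np.ndarray:
        return np.array([e.theta for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "sample_id": self.model.sample_ids,
            "theta": [e.theta for e in self.estimates],
            "loglik": [e.loglik for e in self.estimates],
            "n_markers_used": [e.n_markers_used for e in self.estimates],
            "converged": [e.converged for e in self.estimates],
        }
        if self.model.is_case is not None:
            rows["status"] = np.where(self.model.is_case, "case", "control")
        return pd.DataFrame(rows)

    def balance(self) -> AncestryBalance:
        if self.model.is_case is None:
            raise ValueError("no case/control labels attached to the model")
        return ancestry_balance(self.estimates, self.model.is_case)

    def summary(self) -> str:
        lines = [
            "Two-way admixture maximum-likelihood estimates",
            f"  individuals: {len(self.estimates)}   markers: {self.model.panel.n_markers}"
            f"   panel delta: {self.model.panel.delta:.3f}",
            f"  theta mean +- SD: {self.thetas.mean():.3f} +- {self.thetas.std(ddof=1):.3f}",
        ]
        if self.model.is_case is not None:
            b = self.balance()
            lines += [
                f"  cases:    {b.case_mean:.3f} +- {b.case_sd:.3f} (n={b.case_n})",
                f"  controls: {b.control_mean:.3f} +- {b.control_sd:.3f} (n={b.control_n})",
                f"  Welch t = {b.t:.3f}, df = {b.df:.1f}, two-tailed p = {b.p:.3f}",
            ]
        return "\n".join(lines)
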