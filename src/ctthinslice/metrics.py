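"""Image-quality evaluation: PSNR, MSE, SSIM, winner counts, difference
images, Cohen's kappa, and aggregate reports.

All three similarity metrics are computed on unit-scaled images
(stored / 4095) with peak 1, so an MSE of 1e-4 corresponds to exactly
40 dB PSNR.  SSIM uses the original windowed formulation: an 11x11
Gaussian window (sigma 1.5, truncated), stabilisers C1 = (0.01 L)^2 and
C2 = (0.03 L)^2 with dynamic range L = 1, local statistics weighted by
the (normalised) window, and the mean taken over fully valid window
positions only.

Per-slice "winner counts" compare two methods slice by slice: the
PSNR/MSE family has a single winner per slice (lower MSE, equivalently
higher PSNR — the two orderings coincide because PSNR is a strictly
decreasing function of MSE), SSIM a separate one; exact ties are
tallied apart rather than awarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .volume_io import STORED_MAX


# ---------------------------------------------------------------------------
# Per-slice metrics
# ---------------------------------------------------------------------------

def _unit_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a / STORED_MAX, b / STORED_MAX


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error between stored-value slices on the [0,1] scale."""
    ua, ub = _unit_pair(a, b)
    return float(np.mean((ua - ub) ** 2))


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak 1; +inf for identical slices."""
    m = mse(a, b)
    return math.inf if m == 0.0 else 10.0 * math.log10(1.0 / m)


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = (size - 1) // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    w = np.outer(g, g)
    return w / w.sum()


def ssim(a: np.ndarray, b: np.ndarray, *, win_size: int = 11,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Structural similarity index on unit-scaled slices (original form)."""
    ua, ub = _unit_pair(a, b)
    if min(ua.shape) < win_size:
        raise ValueError(f"image {ua.shape} smaller than the {win_size}px window")
    w = _gaussian_window(win_size, sigma)
    pad = (win_size - 1) // 2

    def filt(img):
        return correlate(img, w, mode="constant")[pad:-pad, pad:-pad]

    mu_a, mu_b = filt(ua), filt(ub)
    # weighted second moments (no sample-covariance correction)
    s_aa = filt(ua * ua) - mu_a ** 2
    s_bb = filt(ub * ub) - mu_b ** 2
    s_ab = filt(ua * ub) - mu_a * mu_b
    c1, c2 = k1 ** 2, k2 ** 2  # dynamic range L = 1
    num = (2 * mu_a * mu_b + c1) * (2 * s_ab + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (s_aa + s_bb + c2)
    return float(np.mean(num / den))


@dataclass(frozen=True)
class MetricTriple:
    """PSNR (dB, may be +inf), MSE ([0,1] scale), SSIM for one slice."""

    psnr: float
    mse: float
    ssim: float


def score_slice(pred: np.ndarray, truth: np.ndarray) -> MetricTriple:
    return MetricTriple(psnr=psnr(pred, truth), mse=mse(pred, truth),
                        ssim=ssim(pred, truth))


def score_volume(pred_voxels: np.ndarray, truth_voxels: np.ndarray) -> list[MetricTriple]:
    if pred_voxels.shape != truth_voxels.shape:
        raise ValueError("volumes must share a shape")
    return [score_slice(p, t) for p, t in zip(pred_voxels, truth_voxels)]


# ---------------------------------------------------------------------------
# Winner counts (per-slice method comparison)
# ---------------------------------------------------------------------------

def winner_counts(triples_m1: list[MetricTriple],
                  triples_m2: list[MetricTriple]) -> dict:
    """Count, per metric family, the slices where each method is better.

    The PSNR/MSE family is counted once (lower MSE wins; the PSNR
    ordering is identical).  Exact ties go to a separate tally.
    """
    if len(triples_m1) != len(triples_m2):
        raise ValueError("slice lists must have equal length")
    counts = {"psnr_mse": {"method1": 0, "method2": 0, "tie": 0},
              "ssim": {"method1": 0, "method2": 0, "tie": 0}}
    for t1, t2 in zip(triples_m1, triples_m2):
        fam = counts["psnr_mse"]
        if t1.mse < t2.mse:
            fam["method1"] += 1
        elif t2.mse < t1.mse:
            fam["method2"] += 1
        else:
            fam["tie"] += 1
        fam = counts["ssim"]
        if t1.ssim > t2.ssim:
            fam["method1"] += 1
        elif t2.ssim > t1.ssim:
            fam["method2"] += 1
        else:
            fam["tie"] += 1
    return counts


# ---------------------------------------------------------------------------
# Signed difference images
# ---------------------------------------------------------------------------

def difference_image(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed difference a - b (stored units) and a red/blue render.

    Positive differences render red, negative blue, zero black; channel
    intensity is scaled symmetrically by max |difference|.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    signed = a - b
    render = np.zeros((*signed.shape, 3), dtype=np.uint8)
    peak = np.abs(signed).max()
    if peak > 0:
        scale = 255.0 / peak
        render[..., 0] = np.clip(signed, 0, None) * scale + 0.5
        render[..., 2] = np.clip(-signed, 0, None) * scale + 0.5
    return signed, render


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def cohen_kappa(ratings1, ratings2) -> float:
    """Cohen's kappa for two raters over categorical items.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the raters' marginal products.  When both
    raters use a single category (p_e = 1) the statistic is degenerate:
    perfect agreement returns 1.0, anything else is an error.
    """
    r1, r2 = list(ratings1), list(ratings2)
    if len(r1) != len(r2):
        raise ValueError("rating lists must have equal length")
    if not r1:
        raise ValueError("empty rating lists")
    n = len(r1)
    cats = sorted(set(r1) | set(r2), key=str)
    p_o = sum(x == y for x, y in zip(r1, r2)) / n
    p_e = sum((r1.count(c) / n) * (r2.count(c) / n) for c in cats)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("degenerate ratings: chance agreement is 1 but observed is not")
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Aggregate reports
# ---------------------------------------------------------------------------

def _finite_mean(values: list[float]) -> tuple[float, int]:
    """Mean excluding +inf entries; returns (mean, number excluded)."""
    finite = [v for v in values if math.isfinite(v)]
    excluded = len(values) - len(finite)
    if not finite:
        return math.inf, excluded
    return float(np.mean(finite)), excluded


@dataclass
class CaseResult:
    """Per-slice metric triples of one case under one method."""

    case_id: str
    triples: list[MetricTriple]

    def means(self) -> dict:
        psnr_mean, n_inf = _finite_mean([t.psnr for t in self.triples])
        return {
            "psnr": psnr_mean,
            "psnr_inf_excluded": n_inf,
            "mse": float(np.mean([t.mse for t in self.triples])),
            "ssim": float(np.mean([t.ssim for t in self.triples])),
            "n_slices": len(self.triples),
        }


@dataclass
class MetricReport:
    """Per-case and aggregate metrics, optionally comparing two methods.

    ``per_case`` maps method tag -> list of :class:`CaseResult`.  Grand
    means are reported both pooled over slices and as the mean of
    per-case means (they differ when case sizes differ).
    """

    per_case: dict[int, list[CaseResult]]
    winner_counts_per_case: dict[str, dict] = field(default_factory=dict)

    def case_means(self, method: int) -> dict[str, dict]:
        return {cr.case_id: cr.means() for cr in self.per_case[method]}

    def grand_means(self, method: int) -> dict:
        all_triples = [t for cr in self.per_case[method] for t in cr.triples]
        pooled_psnr, n_inf = _finite_mean([t.psnr for t in all_triples])
        case_means = [cr.means() for cr in self.per_case[method]]
        return {
            "pooled": {
                "psnr": pooled_psnr,
                "psnr_inf_excluded": n_inf,
                "mse": float(np.mean([t.mse for t in all_triples])),
                "ssim": float(np.mean([t.ssim for t in all_triples])),
                "n_slices": len(all_triples),
            },
            "mean_of_case_means": {
                "psnr": float(np.mean([m["psnr"] for m in case_means])),
                "mse": float(np.mean([m["mse"] for m in case_means])),
                "ssim": float(np.mean([m["ssim"] for m in case_means])),
                "n_cases": len(case_means),
            },
        }

    def total_winner_counts(self) -> dict:
        total = {"psnr_mse": {"method1": 0, "method2": 0, "tie": 0},
                 "ssim": {"method1": 0, "method2": 0, "tie": 0}}
        for counts in self.winner_counts_per_case.values():
            for fam in total:
                for key in total[fam]:
                    total[fam][key] += counts[fam][key]
        return total

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "per_case": {
                str(m): [{"case_id": cr.case_id,
                          "triples": [[t.psnr, t.mse, t.ssim] for t in cr.triples]}
                         for cr in crs]
                for m, crs in self.per_case.items()
            },
            "winner_counts_per_case": self.winner_counts_per_case,
        }

    def to_json(self) -> str:
        def encode(o):
            if isinstance(o, float) and math.isinf(o):
                return "Infinity"
            raise TypeError
        return json.dumps(self.to_dict(), indent=2,
                          default=encode).replace('"Infinity"', "1e999")

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        per_case = {
            int(m): [CaseResult(case_id=rec["case_id"],
                                triples=[MetricTriple(*t) for t in rec["triples"]])
                     for rec in recs]
            for m, recs in d["per_case"].items()
        }
        return cls(per_case=per_case,
                   winner_counts_per_case=d.get("winner_counts_per_case", {}))

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        return cls.from_dict(json.loads(text))

    def to_csv(self) -> str:
        lines = ["method,case_id,slice,psnr,mse,ssim"]
        for m, crs in sorted(self.per_case.items()):
            for cr in crs:
                for i, t in enumerate(cr.triples):
                    lines.append(f"{m},{cr.case_id},{i},{t.psnr!r},{t.mse!r},{t.ssim!r}")
        return "\n".join(lines) + "\n"


def metric_report(case_results: dict[int, list[CaseResult]]) -> MetricReport:
    """Assemble a report; winner counts are filled when both methods share
    cases with equal slice counts."""
    if not case_results or not any(case_results.values()):
        raise ValueError("empty input")
    report = MetricReport(per_case=case_results)
    if 1 in case_results and 2 in case_results:
        by_id_1 = {cr.case_id: cr for cr in case_results[1]}
        by_id_2 = {cr.case_id: cr for cr in case_results[2]}
        for cid in by_id_1.keys() & by_id_2.keys():
            if len(by_id_1[cid].triples) == len(by_id_2[cid].triples):
                report.winner_counts_per_case[cid] = winner_counts(
                    by_id_1[cid].triples, by_id_2[cid].triples)
    return report
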