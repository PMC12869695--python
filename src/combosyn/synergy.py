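"""Dose-response synergy scoring: Bliss, HSA, Loewe and ZIP excesses.

A block is a complete checkerboard of % inhibition values for one drug
pair in one sample, with dose-0 monotherapy margins.  Each scorer
compares the observed interior wells with a null-model expectation built
from the single agents and returns the *mean* excess over interior
wells, so scores are grid-size independent:

* Bliss — probabilistic independence: E = yA + yB - yA*yB/100.
* HSA  — highest single agent: E = max(yA, yB).
* Loewe — dose additivity: E solves d1/DA(E) + d2/DB(E) = 1 where DA,
  DB invert fitted Hill curves (bisection; HSA fallback where the
  dose-equivalence equation has no root in range).
* ZIP  — a conditional-fit delta: re-fit each row and column with the
  opposing monotherapy as a fixed baseline and compare the mean fitted
  response against the Bliss surface of the fitted monotherapies.
  (This is a documented simplification of the full published ZIP; see
  docs/methods.md.)

Labels follow the strict-exceedance rule: synergistic iff the Loewe
excess is > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseBlock", "HillFit", "SynergyRecord",
    "fit_hill", "bliss_excess", "hsa_excess", "loewe_excess", "zip_delta",
    "score_block", "binarize", "average_duplicates",
]

_LOEWE_TOL = 1e-6
_LOEWE_MAXIT = 100


@dataclass
class DoseResponseBlock:
    drug_a: str
    drug_b: str
    sample: str
    conc_a: np.ndarray   # increasing, conc_a[0] == 0
    conc_b: np.ndarray
    response: np.ndarray  # |conc_a| x |conc_b| % inhibition

    def __post_init__(self):
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (len(self.conc_a), len(self.conc_b)):
            raise ValueError("response shape does not match concentrations")
        for c in (self.conc_a, self.conc_b):
            if c[0] != 0 or np.any(np.diff(c) <= 0):
                raise ValueError("concentrations must be strictly increasing "
                                 "with first dose 0")
        if np.any(~np.isfinite(self.response)):
            raise ValueError("block has missing or non-finite wells")

    def transposed(self) -> "DoseResponseBlock":
        return DoseResponseBlock(drug_a=self.drug_b, drug_b=self.drug_a,
                                 sample=self.sample, conc_a=self.conc_b.copy(),
                                 conc_b=self.conc_a.copy(),
                                 response=self.response.T.copy())

    @property
    def margin_a(self) -> np.ndarray:
        """Monotherapy responses of drug_a (column at conc_b = 0)."""
        return self.response[:, 0]

    @property
    def margin_b(self) -> np.ndarray:
        return self.response[0, :]


@dataclass
class HillFit:
    e_max: float
    ec50: float
    h: float
    baseline: float = 0.0
    converged: bool = True

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = (self.baseline + (self.e_max - self.baseline)
                 * dose ** self.h / (self.ec50 ** self.h + dose ** self.h))
        return np.where(dose > 0, y, self.baseline)

    def inverse(self, y: float) -> float:
        """Dose producing inhibition y; inf if y is out of reach."""
        if y <= self.baseline:
            return 0.0
        if y >= self.e_max:
            return np.inf
        frac = (y - self.baseline) / (self.e_max - y)
        return self.ec50 * frac ** (1.0 / self.h)


@dataclass
class SynergyRecord:
    drug_a: str
    drug_b: str
    sample: str
    score_loewe: float
    score_bliss: float
    score_hsa: float
    score_zip: float
    label: int

    def canonical(self) -> "SynergyRecord":
        if self.drug_a <= self.drug_b:
            return self
        return replace(self, drug_a=self.drug_b, drug_b=self.drug_a)

    @property
    def key(self):
        a, b = sorted((self.drug_a, self.drug_b))
        return (a, b, self.sample)


def _hill_model(d, e_max, log_ec50, h, baseline):
    ec50 = np.exp(log_ec50)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = baseline + (e_max - baseline) * d ** h / (ec50 ** h + d ** h)
    return np.where(d > 0, y, baseline)


def _fallback_fit(doses, responses, baseline: float) -> HillFit:
    """Median-interpolation fallback when the optimizer fails."""
    nz = doses > 0
    e_max = float(np.clip(np.max(responses[nz], initial=0.0), 0.0, 120.0))
    half = baseline + (e_max - baseline) / 2.0
    above = doses[nz][responses[nz] >= half]
    ec50 = float(above.min()) if above.size else float(np.median(doses[nz]))
    ec50 = max(ec50, 1e-9)
    return HillFit(e_max=e_max, ec50=ec50, h=1.0, baseline=baseline,
                   converged=False)


def fit_hill(doses, responses, baseline_fixed: float | None = None) -> HillFit:
    """Least-squares four-parameter Hill fit of % inhibition vs dose.

    y = b + (e_max - b) * d^h / (ec50^h + d^h), with the baseline b fixed
    at 0 unless `baseline_fixed` is given (conditional ZIP fits).  Bounds:
    e_max in [0, 120], h in (0.1, 10].  On optimizer failure a
    median-interpolation fallback is returned with converged=False.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.count_nonzero(np.unique(doses) > 0) < 3:
        raise ValueError("fit_hill requires at least 3 distinct nonzero doses")
    b = 0.0 if baseline_fixed is None else float(baseline_fixed)

    nz = doses[doses > 0]
    if np.all(np.abs(responses - b) < 1e-9):
        # flat series: a null drug; the curve is identically the baseline
        return HillFit(e_max=b, ec50=float(np.median(nz)), h=1.0,
                       baseline=b, converged=True)
    mid = np.median(np.log(nz))
    lo = np.log(nz.min()) - np.log(100.0)
    hi = np.log(nz.max()) + np.log(100.0)
    e0 = float(np.clip(responses.max(initial=1.0), max(b + 1e-3, 1.0), 120.0))
    try:
        popt, _ = curve_fit(
            lambda d, e, lec, h: _hill_model(d, e, lec, h, b),
            doses, responses, p0=[e0, mid, 1.0],
            bounds=([max(b, 0.0), lo, 0.101], [120.0, hi, 10.0]),
            maxfev=5000)
        e_max, lec, h = popt
        fit = HillFit(e_max=float(e_max), ec50=float(np.exp(lec)),
                      h=float(h), baseline=b, converged=True)
        resid = responses - fit.predict(doses)
        # guard against a formally "converged" fit that explains nothing
        # on strongly non-monotone (e.g. inverted) response series
        if np.corrcoef(responses[doses > 0], doses[doses > 0])[0, 1] < -0.5 \
                and np.mean(np.abs(resid)) > 5.0:
            return _fallback_fit(doses, responses, b)
        return fit
    except (RuntimeError, ValueError):
        return _fallback_fit(doses, responses, b)


def _interior(block: DoseResponseBlock):
    return block.response[1:, 1:]


def bliss_excess(block: DoseResponseBlock) -> float:
    ya = block.margin_a[1:]
    yb = block.margin_b[1:]
    expected = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :] / 100.0
    return float(np.mean(_interior(block) - expected))


def hsa_excess(block: DoseResponseBlock) -> float:
    ya = block.margin_a[1:]
    yb = block.margin_b[1:]
    expected = np.maximum(ya[:, None], yb[None, :])
    return float(np.mean(_interior(block) - expected))


def _loewe_expected(d1: float, d2: float, fa: HillFit, fb: HillFit) -> float:
    """Solve d1/DA(y) + d2/DB(y) = 1 for y by bisection; nan if no root."""
    top = min(fa.e_max, fb.e_max)
    if top <= 0:
        return np.nan

    def f(y):
        da, db = fa.inverse(y), fb.inverse(y)
        s = 0.0
        if d1 > 0:
            if da == 0.0:
                return np.inf
            s += d1 / da
        if d2 > 0:
            if db == 0.0:
                return np.inf
            s += d2 / db
        return s - 1.0

    lo, hi = 1e-9, top - 1e-9
    flo, fhi = f(lo), f(hi)
    if not (np.isfinite(flo) or flo == np.inf) or np.isnan(fhi):
        return np.nan
    if fhi > 0:      # no root below the weaker e_max (saturated doses)
        return np.nan
    if flo < 0:      # no root in range: doses too small to reach any y
        return np.nan
    for _ in range(_LOEWE_MAXIT):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < _LOEWE_TOL:
            break
        if fm > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _monotherapy_fits(block: DoseResponseBlock):
    errors = []
    fits = []
    for doses, resp in ((block.conc_a, block.margin_a),
                        (block.conc_b, block.margin_b)):
        try:
            fits.append(fit_hill(doses, resp))
        except ValueError as exc:
            errors.append(str(exc))
            fits.append(None)
    if all(f is None for f in fits):
        raise ValueError("both monotherapy fits failed: " + "; ".join(errors))
    return fits


def loewe_excess(block: DoseResponseBlock) -> float:
    fa, fb = _monotherapy_fits(block)
    if fa is None or fb is None:
        raise ValueError("loewe_excess requires both monotherapy fits")
    ya = block.margin_a
    yb = block.margin_b
    obs = block.response
    total, count = 0.0, 0
    for i in range(1, len(block.conc_a)):
        for j in range(1, len(block.conc_b)):
            exp = _loewe_expected(block.conc_a[i], block.conc_b[j], fa, fb)
            if np.isnan(exp):
                exp = max(ya[i], yb[j])   # HSA fallback
            total += obs[i, j] - exp
            count += 1
    return total / count


def zip_delta(block: DoseResponseBlock) -> float:
    """Conditional-fit potency-shift delta against the fitted Bliss surface."""
    fa, fb = _monotherapy_fits(block)
    if fa is None or fb is None:
        raise ValueError("zip_delta requires both monotherapy fits")
    na, nb = len(block.conc_a), len(block.conc_b)
    ya_hat = fa.predict(block.conc_a)
    yb_hat = fb.predict(block.conc_b)

    # conditional fits along rows (vary conc_a at fixed conc_b=j)
    row_fit = np.empty((na, nb))
    for j in range(1, nb):
        try:
            fj = fit_hill(block.conc_a, block.response[:, j],
                          baseline_fixed=yb_hat[j])
            row_fit[:, j] = fj.predict(block.conc_a)
        except ValueError:
            row_fit[:, j] = block.response[:, j]
    col_fit = np.empty((na, nb))
    for i in range(1, na):
        try:
            fi = fit_hill(block.conc_b, block.response[i, :],
                          baseline_fixed=ya_hat[i])
            col_fit[i, :] = fi.predict(block.conc_b)
        except ValueError:
            col_fit[i, :] = block.response[i, :]

    expected = (ya_hat[:, None] + yb_hat[None, :]
                - ya_hat[:, None] * yb_hat[None, :] / 100.0)
    fitted = 0.5 * (row_fit[1:, 1:] + col_fit[1:, 1:])
    return float(np.mean(fitted - expected[1:, 1:]))


def central_bliss_excess(block: DoseResponseBlock) -> float:
    """Observed minus Bliss-expected inhibition at the central well.

    The central well is the interior dose index ceil((n-1)/2) on each
    axis — the peak of the synthetic synergy kernel.  Unlike the
    grid-mean scores, this statistic isolates the planted bump.
    """
    ci = int(np.ceil((len(block.conc_a) - 1) / 2))
    cj = int(np.ceil((len(block.conc_b) - 1) / 2))
    ya, yb = block.margin_a[ci], block.margin_b[cj]
    expected = ya + yb - ya * yb / 100.0
    return float(block.response[ci, cj] - expected)


def binarize(score_loewe: float) -> int:
    """Synergistic iff the Loewe excess strictly exceeds 0."""
    return int(score_loewe > 0)


def score_block(block: DoseResponseBlock) -> SynergyRecord:
    """All four synergy scores plus the binary label, drug ids canonical."""
    loewe = loewe_excess(block)
    rec = SynergyRecord(drug_a=block.drug_a, drug_b=block.drug_b,
                        sample=block.sample,
                        score_loewe=loewe,
                        score_bliss=bliss_excess(block),
                        score_hsa=hsa_excess(block),
                        score_zip=zip_delta(block),
                        label=binarize(loewe))
    return rec.canonical()


def average_duplicates(records) -> list:
    """Collapse records sharing a canonical triplet key to mean scores.

    The label is recomputed from the averaged Loewe score.  First-seen
    order of keys is preserved.
    """
    grouped: dict = {}
    order = []
    for rec in records:
        key = rec.key
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(rec.canonical())
    out = []
    for key in order:
        grp = grouped[key]
        loewe = float(np.mean([r.score_loewe for r in grp]))
        out.append(SynergyRecord(
            drug_a=key[0], drug_b=key[1], sample=key[2],
            score_loewe=loewe,
            score_bliss=float(np.mean([r.score_bliss for r in grp])),
            score_hsa=float(np.mean([r.score_hsa for r in grp])),
            score_zip=float(np.mean([r.score_zip for r in grp])),
            label=binarize(loewe)))
    return out
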