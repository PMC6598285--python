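"""Spectrum-to-protein quantitation for 4-plex reporter-ion data.

The pipeline applies, in order:

1. isotope cross-over correction of the four reporter intensities against a
   reagent purity matrix (non-negative least squares, so noisy spectra can
   never acquire negative intensities);
2. spectrum qualification: labeled, target-database peptide with
   log10(e) <= -2.0;
3. per-comparison normalization to the ratio of summed corrected intensities
   over all qualifying spectra (equal-loading assumption);
4. per-spectrum ratios with the "Divide 0" sentinel: a zero denominator with a
   positive numerator is recorded as the fixed placeholder 10 instead of a
   rescaled ratio;
5. per-protein pairwise median ratios over spectra whose two-channel corrected
   intensity sum exceeds 20,000;
6. a one-sample location test of the log2 ratios against 0;
7. the quantitation gate: >= 3 contributing spectra and p <= 0.01.

All thresholds default to the published values and live in :class:`QuantConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .io import CHANNELS, PSMRecord, _fmt, _reading, _rows, _writing

DEFAULT_COMPARISONS = ("115/114", "116/114", "117/114")

STATUS_QUANTIFIED = "quantified"
STATUS_INSUFFICIENT_PSM = "insufficient_psm"
STATUS_NOT_SIGNIFICANT = "not_significant"
PROTEIN_STATUSES = (STATUS_QUANTIFIED, STATUS_INSUFFICIENT_PSM, STATUS_NOT_SIGNIFICANT)

# Largest sample size for which the signed-rank null is built by full sign-flip
# enumeration (2^n assignments); tie-safe, unlike the classical exact tables.
_ENUM_MAX = 14
_COND_MAX = 1e12


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and choices of the quantitation stage (defaults = published values)."""

    log_e_max: float = -2.0
    intensity_sum_min: float = 20_000.0
    sentinel_ratio: float = 10.0
    min_psm: int = 3
    p_max: float = 0.01
    test: str = "wilcoxon"  # or "ttest"
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS

    def validate(self) -> None:
        if self.sentinel_ratio <= 0:
            raise ConfigurationError("sentinel_ratio must be positive")
        if self.intensity_sum_min < 0:
            raise ConfigurationError("intensity_sum_min must be >= 0")
        if self.min_psm < 1:
            raise ConfigurationError("min_psm must be >= 1")
        if not 0 < self.p_max <= 1:
            raise ConfigurationError("p_max must be in (0, 1]")
        if self.test not in ("wilcoxon", "ttest"):
            raise ConfigurationError(f"unknown test {self.test!r}")
        for comp in self.comparisons:
            comparison_channels(comp)


def comparison_channels(comparison: str) -> tuple[int, int]:
    """Map a comparison label like '115/114' to (numerator, denominator) channel indices."""
    try:
        num, den = comparison.split("/")
        return CHANNELS.index(int(num)), CHANNELS.index(int(den))
    except (ValueError, IndexError):
        raise ConfigurationError(
            f"comparison must be '<channel>/<channel>' over {CHANNELS}, got {comparison!r}"
        ) from None


class PurityMatrix:
    """4x4 reagent purity matrix P; P[r, c] = fraction of channel c's signal seen in channel r.

    Column sums may be below 1 (signal falling outside the four windows);
    diagonal entries must be at least 0.8 for a plausible reagent lot.
    """

    def __init__(self, matrix) -> None:
        arr = np.asarray(matrix, dtype=float)
        if arr.shape != (4, 4):
            raise ConfigurationError(f"purity matrix must be 4x4, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ConfigurationError("purity matrix entries must be finite and >= 0")
        if np.any(arr.sum(axis=0) > 1 + 1e-9):
            raise ConfigurationError("purity matrix column sums must not exceed 1")
        if np.any(np.diag(arr) < 0.8):
            raise ConfigurationError("purity matrix diagonal entries must be >= 0.8")
        self._m = arr

    @property
    def matrix(self) -> np.ndarray:
        return self._m.copy()

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self._m, dtype=dtype)

    @classmethod
    def identity(cls) -> "PurityMatrix":
        return cls(np.eye(4))

    @classmethod
    def default(cls) -> "PurityMatrix":
        """Typical 4-plex reagent certificate: 93% on-channel, 6% at +1 Da, 1% at -1 Da.

        Lot certificates vary; override with the matrix supplied for the actual
        reagent lot whenever one is available.
        """
        m = np.zeros((4, 4))
        for c in range(4):
            m[c, c] = 0.93
            if c + 1 < 4:
                m[c + 1, c] = 0.06
            if c - 1 >= 0:
                m[c - 1, c] = 0.01
        return cls(m)

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "PurityMatrix":
        """Read a channel-labeled 4x4 purity table (header: channel i114..i117)."""
        with _reading(source) as fh:
            rows = list(_rows(fh))
        if len(rows) != 5:
            raise ConfigurationError("purity table must have a header and 4 data rows")
        m = np.zeros((4, 4))
        for r, (lineno, fields) in enumerate(rows[1:]):
            if len(fields) < 5:
                raise ConfigurationError(f"purity table line {lineno}: expected 5 fields")
            m[r] = [float(v) for v in fields[1:5]]
        return cls(m)

    def to_tsv(self, sink: str | Path | IO[str]) -> None:
        with _writing(sink) as fh:
            fh.write("channel\t" + "\t".join(f"i{c}" for c in CHANNELS) + "\n")
            for r, ch in enumerate(CHANNELS):
                fh.write(f"i{ch}\t" + "\t".join(_fmt(v) for v in self._m[r]) + "\n")


@dataclass(frozen=True)
class SpectrumRatio:
    """Ratio carried by one spectrum for one channel comparison."""

    spectrum_id: str
    comparison: str
    raw_ratio: float | None  # None for sentinel spectra (undefined raw ratio)
    normalized_ratio: float
    is_sentinel: bool
    channel_sum: float  # corrected numerator + denominator intensity


@dataclass(frozen=True)
class ProteinQuant:
    """Per-protein, per-comparison quantitation result."""

    protein_acc: str
    comparison: str
    median_ratio: float
    n_psm: int
    p_value: float
    status: str


def _check_purity(purity: PurityMatrix) -> np.ndarray:
    P = np.asarray(purity, dtype=float)
    if np.linalg.cond(P) > _COND_MAX:
        raise ConfigurationError("purity matrix is singular or near-singular")
    return P


def correct_isotope_crossover(intensities: Sequence[float], purity: PurityMatrix) -> np.ndarray:
    """Recover true reporter intensities from observed ones.

    Solves min ||P t - observed||_2 subject to t >= 0, which coincides with the
    plain inverse on consistent data but never produces negative intensities on
    noisy spectra.
    """
    P = _check_purity(purity)
    obs = np.asarray(intensities, dtype=float)
    if obs.shape != (4,):
        raise ValidationError(f"expected 4 intensities, got shape {obs.shape}")
    if not np.all(np.isfinite(obs)) or np.any(obs < 0):
        raise ValidationError("intensities must be finite and >= 0")
    if not obs.any():
        return np.zeros(4)
    t, _ = optimize.nnls(P, obs)
    return t


def _correct_matrix(X: np.ndarray, purity: PurityMatrix) -> np.ndarray:
    """Vectorized correction: plain solve, with an NNLS fallback for rows that go negative."""
    P = _check_purity(purity)
    T = np.linalg.solve(P, X.T).T
    scale = np.maximum(X.max(axis=1, initial=0.0), 1.0)
    bad = np.where((T < -1e-9 * scale[:, None]).any(axis=1))[0]
    for i in bad:
        T[i], _ = optimize.nnls(P, X[i])
    return np.clip(T, 0.0, None)


def passes_spectrum_criteria(psm: PSMRecord, config: QuantConfig | None = None) -> bool:
    """Spectrum qualification: 4-plex label present, target-database hit, log10(e) <= -2.0."""
    cfg = config or QuantConfig()
    return bool(psm.has_label and psm.in_target_db and psm.log_e <= cfg.log_e_max)


def normalization_factor(
    corrected_intensities: Sequence[Sequence[float]] | np.ndarray, comparison: str
) -> float:
    """Summed-intensity normalization factor over qualifying, corrected spectra.

    Returns (sum of numerator-channel intensities) / (sum of denominator-channel
    intensities); dividing each spectrum ratio by this factor enforces the
    equal-loading assumption (total signal per channel is comparable).
    """
    X = np.atleast_2d(np.asarray(corrected_intensities, dtype=float))
    if X.shape[0] == 0 or X.shape[1] != 4:
        raise DegenerateInputError("need at least one corrected 4-channel spectrum")
    ni, di = comparison_channels(comparison)
    den = float(X[:, di].sum())
    num = float(X[:, ni].sum())
    if den <= 0:
        raise DegenerateInputError(f"comparison {comparison}: zero denominator channel sum")
    if num <= 0:
        raise DegenerateInputError(f"comparison {comparison}: zero numerator channel sum")
    return num / den


def spectrum_ratio(
    psm: PSMRecord,
    comparison: str,
    norm: float,
    config: QuantConfig | None = None,
) -> SpectrumRatio | None:
    """Normalized ratio of one (already corrected) spectrum, or None when undefined.

    A zero denominator with positive numerator gets the fixed sentinel value
    (default 10) in place of a normalized ratio — the sentinel is a final
    placeholder, not a raw value to rescale.  Spectra with zero numerator carry
    no finite positive ratio and are excluded entirely, as are 0/0 spectra.
    """
    cfg = config or QuantConfig()
    if norm <= 0:
        raise DegenerateInputError("normalization factor must be positive")
    ni, di = comparison_channels(comparison)
    i_num = psm.intensities[ni]
    i_den = psm.intensities[di]
    if i_num == 0:
        return None
    channel_sum = i_num + i_den
    if i_den == 0:
        return SpectrumRatio(
            spectrum_id=psm.spectrum_id,
            comparison=comparison,
            raw_ratio=None,
            normalized_ratio=cfg.sentinel_ratio,
            is_sentinel=True,
            channel_sum=channel_sum,
        )
    raw = i_num / i_den
    return SpectrumRatio(
        spectrum_id=psm.spectrum_id,
        comparison=comparison,
        raw_ratio=raw,
        normalized_ratio=raw / norm,
        is_sentinel=False,
        channel_sum=channel_sum,
    )


def protein_median_ratio(
    ratios: Iterable[SpectrumRatio], intensity_sum_min: float = 20_000.0
) -> tuple[float, int] | None:
    """Median normalized ratio over spectra passing the two-channel intensity filter.

    The filter is strict (channel_sum > threshold).  Returns (median, n), or
    None when no spectrum passes.  Even n takes the midpoint of the two central
    values.
    """
    vals = sorted(r.normalized_ratio for r in ratios if r.channel_sum > intensity_sum_min)
    if not vals:
        return None
    return float(np.median(vals)), len(vals)


def _signflip_exact_p(x: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign assignments.

    Uses average ranks, so tied |x| values (common on idealized data) are
    handled exactly rather than approximately.
    """
    ranks = stats.rankdata(np.abs(x))
    w_obs = float(ranks[x > 0].sum())
    n = len(x)
    # all subsets via bit matrix: row s, column i -> sign of x_i in assignment s
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = bits @ ranks
    n_le = int(np.count_nonzero(w_all <= w_obs + 1e-12))
    n_ge = int(np.count_nonzero(w_all >= w_obs - 1e-12))
    return min(1.0, 2.0 * min(n_le, n_ge) / 2**n)


def protein_p_value(log2_ratios: Sequence[float], test: str = "wilcoxon") -> float:
    """Two-sided p-value of a one-sample location test of log2 ratios against 0.

    Default is the Wilcoxon signed-rank test with an exact null for small n
    (full sign-flip enumeration up to n=14, classical exact distribution up to
    n=25 when |x| are untied); a one-sample t-test is selectable.  An all-zero
    sample is perfectly consistent with no change: p = 1 by convention.
    """
    x = np.asarray(log2_ratios, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("need at least one log2 ratio")
    if not np.all(np.isfinite(x)):
        raise ValidationError("log2 ratios must be finite")
    if np.all(x == 0):
        return 1.0
    if test == "ttest":
        if np.all(x == x[0]):
            # zero variance, nonzero mean: the t statistic diverges
            return 0.0
        return float(stats.ttest_1samp(x, 0.0).pvalue)
    if test != "wilcoxon":
        raise ConfigurationError(f"unknown test {test!r}")
    nz = x[x != 0]  # classical zero-handling: drop exact zeros
    if nz.size == 0:
        return 1.0
    if nz.size <= _ENUM_MAX:
        return _signflip_exact_p(nz)
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= 25 and not has_ties:
        return float(stats.wilcoxon(nz, method="exact").pvalue)
    return float(stats.wilcoxon(nz, method="approx", correction=True).pvalue)


def quantify_proteins(
    psms: Iterable[PSMRecord],
    purity: PurityMatrix | None = None,
    config: QuantConfig | None = None,
) -> list[ProteinQuant]:
    """Run the full spectrum-to-protein quantitation and return one record per
    protein per comparison (proteins with no ratio-bearing spectrum in a
    comparison emit nothing for it)."""
    cfg = config or QuantConfig()
    cfg.validate()
    purity = purity or PurityMatrix.default()
    records = list(psms)
    if not records:
        return []

    X = np.array([r.intensities for r in records], dtype=float)
    C = _correct_matrix(X, purity)
    qual = np.array([passes_spectrum_criteria(r, cfg) for r in records], dtype=bool)
    prot = np.array([r.protein_acc for r in records])

    # group row indices by protein once
    by_protein: dict[str, list[int]] = {}
    for i, acc in enumerate(prot):
        by_protein.setdefault(acc, []).append(i)

    out: list[ProteinQuant] = []
    for comp in cfg.comparisons:
        ni, di = comparison_channels(comp)
        num, den = C[:, ni], C[:, di]
        den_sum = float(den[qual].sum())
        num_sum = float(num[qual].sum())
        if den_sum <= 0 or num_sum <= 0:
            raise DegenerateInputError(
                f"comparison {comp}: zero summed intensity over qualifying spectra"
            )
        norm = num_sum / den_sum

        valid = qual & (num > 0)
        sent = valid & (den == 0)
        ratio = np.zeros(len(records))
        finite = valid & ~sent
        ratio[finite] = (num[finite] / den[finite]) / norm
        ratio[sent] = cfg.sentinel_ratio
        csum = num + den
        passing = valid & (csum > cfg.intensity_sum_min)

        for acc in sorted(by_protein):
            idx = np.array(by_protein[acc])
            keep = idx[passing[idx]]
            if keep.size == 0:
                continue
            median = float(np.median(ratio[keep]))
            n_psm = int(keep.size)
            testable = keep[~sent[keep]]
            if testable.size:
                p = protein_p_value(np.log2(ratio[testable]), test=cfg.test)
            else:
                p = 1.0  # only sentinel imputations passed: nothing to test
            if n_psm < cfg.min_psm:
                status = STATUS_INSUFFICIENT_PSM
            elif p <= cfg.p_max:
                status = STATUS_QUANTIFIED
            else:
                status = STATUS_NOT_SIGNIFICANT
            out.append(
                ProteinQuant(
                    protein_acc=acc,
                    comparison=comp,
                    median_ratio=median,
                    n_psm=n_psm,
                    p_value=p,
                    status=status,
                )
            )
    out.sort(key=lambda q: (q.protein_acc, q.comparison))
    return out
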