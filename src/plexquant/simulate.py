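"""Synthetic 4-plex PSM tables with known ground truth.

The generator emulates the data structure of a 4-plex reporter-ion experiment
over a control and three stress conditions (channels 114, 115, 116, 117 mapped
to 0, 50, 100, 200 mM exogenous ethanol): per-protein planted fold changes, a
log-normal base intensity per spectrum, multiplicative log-normal noise per
stress channel, and the defects a real run exhibits — occasional zero channels,
spectra below the intensity-sum filter, low-confidence identifications,
unlabeled peptides, and peptides outside the target database.  Channel
cross-contamination is applied last, through a purity matrix, mirroring the
instrument (leakage happens after the sample state is fixed).

Every quantity needed to score the downstream pipeline is recorded in
:class:`GroundTruth`, including the normalization-adjusted expected ratios: the
summed-intensity normalization reports each protein relative to the
intensity-weighted population average, so that — not the raw planted value —
is what an ideal pipeline returns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import COG_ALPHABET, AnnotationMap, PSMRecord
from .quant import DEFAULT_COMPARISONS, PurityMatrix, comparison_channels

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


def protein_ids(n: int) -> list[str]:
    """Deterministic synthetic accessions P0001, P0002, ..."""
    return [f"P{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.  Defaults are the benchmark conditions used throughout:

    500 proteins with 20 spectra each, per-spectrum multiplicative noise of
    0.25 log2 units on each stress channel, 20% of proteins planted at a
    |fold change| of 1.6 (half up, half down, same sign in all three stress
    conditions), and low rates of the defect classes seen in real runs.
    """

    n_proteins: int = 500
    psm_min: int = 20
    psm_max: int = 20
    frac_de: float = 0.2
    de_log2_fc: float = math.log2(1.6)
    true_log2_fc: Mapping[str, Sequence[float]] | None = None  # overrides planting
    noise_sd_log2: float = 0.25
    purity: PurityMatrix | None = None  # None = no cross-contamination
    base_intensity: float = 2e5
    base_log2_sd: float = 1.0
    frac_zero_channel: float = 0.02
    frac_low_quality: float = 0.05
    frac_unlabeled: float = 0.03
    frac_offdb: float = 0.05
    frac_low_intensity: float = 0.05
    low_intensity_total: float = 10_000.0  # total 4-channel signal of a "dim" spectrum
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if not 1 <= self.psm_min <= self.psm_max:
            raise ConfigurationError("need 1 <= psm_min <= psm_max")
        if self.noise_sd_log2 < 0 or self.base_log2_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.base_intensity <= 0 or self.low_intensity_total <= 0:
            raise ConfigurationError("intensities must be positive")
        for name in (
            "frac_de",
            "frac_zero_channel",
            "frac_low_quality",
            "frac_unlabeled",
            "frac_offdb",
            "frac_low_intensity",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GroundTruth:
    """Planted values against which pipeline recovery is scored.

    ``ratios`` are the planted design ratios (2**log2_fc); ``expected_ratios``
    are the same values divided by the per-comparison normalization factor the
    pipeline will compute, i.e. what an ideal (noise-free, defect-free)
    pipeline reports; ``de_direction`` applies the published thresholds
    (up >= 1.2, down <= 0.83) to the planted ratios.
    """

    log2_fc: pd.DataFrame  # protein x comparison
    ratios: pd.DataFrame
    expected_ratios: pd.DataFrame
    de_direction: pd.DataFrame
    norm_factors: dict[str, float]
    pre_mix_intensities: pd.DataFrame  # spectrum x channel, after defects, before leakage

    def de_accessions(self, comparison: str) -> set[str]:
        col = self.de_direction[comparison]
        return set(col.index[col != DIRECTION_NONE])


def _direction(ratio: float, up: float = 1.2, down: float = 0.83) -> str:
    if ratio >= up:
        return DIRECTION_UP
    if ratio <= down:
        return DIRECTION_DOWN
    return DIRECTION_NONE


def _planted_log2_fc(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    accs = protein_ids(config.n_proteins)
    comps = list(DEFAULT_COMPARISONS)
    if config.true_log2_fc is not None:
        fc = pd.DataFrame(0.0, index=accs, columns=comps)
        for acc, vals in config.true_log2_fc.items():
            if acc not in fc.index:
                raise ConfigurationError(f"true_log2_fc names unknown protein {acc!r}")
            if len(vals) != len(comps):
                raise ConfigurationError(
                    f"true_log2_fc[{acc!r}] must give {len(comps)} values"
                )
            fc.loc[acc] = list(vals)
        return fc
    n_de = int(round(config.frac_de * config.n_proteins))
    de_idx = rng.choice(config.n_proteins, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    fc = pd.DataFrame(0.0, index=accs, columns=comps)
    for i, s in zip(de_idx, signs):
        fc.iloc[i] = s * config.de_log2_fc
    return fc


def generate_dataset(config: SyntheticConfig) -> tuple[list[PSMRecord], GroundTruth]:
    """Generate a PSM table plus ground truth; a pure function of ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    comps = list(DEFAULT_COMPARISONS)

    fc = _planted_log2_fc(config, rng)
    ratios = 2.0**fc
    accs = list(fc.index)

    counts = rng.integers(config.psm_min, config.psm_max + 1, size=config.n_proteins)
    n_spec = int(counts.sum())
    protein_of = np.repeat(np.arange(config.n_proteins), counts)

    # (1) base channel-114 intensity, (2) stress channels = base * ratio * noise
    base = config.base_intensity * 2.0 ** rng.normal(0.0, config.base_log2_sd, n_spec)
    intens = np.empty((n_spec, 4))
    intens[:, 0] = base
    ratio_rows = ratios.to_numpy()[protein_of]  # n_spec x 3
    for j, comp in enumerate(comps):
        ni, _ = comparison_channels(comp)
        noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, n_spec)
        intens[:, ni] = base * ratio_rows[:, j] * noise

    # (3) defects, acting on the true (pre-leakage) signal
    zero_mask = rng.random(n_spec) < config.frac_zero_channel
    zero_channel = rng.integers(0, 4, size=n_spec)
    intens[zero_mask, zero_channel[zero_mask]] = 0.0
    dim_mask = rng.random(n_spec) < config.frac_low_intensity
    row_tot = intens[dim_mask].sum(axis=1)
    row_tot[row_tot == 0] = 1.0
    intens[dim_mask] *= (config.low_intensity_total / row_tot)[:, None]

    # (5) quality/label/db flags (drawn before mixing; independent of intensities)
    low_q = rng.random(n_spec) < config.frac_low_quality
    log_e = np.where(
        low_q,
        rng.uniform(-1.9, -0.1, n_spec),
        rng.uniform(-8.0, -2.0, n_spec),
    )
    has_label = rng.random(n_spec) >= config.frac_unlabeled
    in_db = rng.random(n_spec) >= config.frac_offdb

    pre_mix = intens.copy()

    # (4) channel cross-contamination
    if config.purity is not None:
        intens = pre_mix @ np.asarray(config.purity).T

    # normalization factors an ideal pipeline computes on this table
    qual = has_label & in_db & (log_e <= -2.0)
    norm_factors: dict[str, float] = {}
    expected = ratios.copy()
    for comp in comps:
        ni, di = comparison_channels(comp)
        den_sum = pre_mix[qual, di].sum()
        num_sum = pre_mix[qual, ni].sum()
        nf = float(num_sum / den_sum) if den_sum > 0 else float("nan")
        norm_factors[comp] = nf
        expected[comp] = ratios[comp] / nf

    de_dir = ratios.map(_direction)

    spectrum_ids = [f"S{i:06d}" for i in range(1, n_spec + 1)]
    pep_len = rng.integers(8, 16, size=config.n_proteins)
    peptides_by_protein = [
        "".join(rng.choice(_AMINO_ACIDS, size=int(k))) for k in pep_len
    ]
    records = [
        PSMRecord(
            spectrum_id=spectrum_ids[i],
            peptide=peptides_by_protein[protein_of[i]],
            protein_acc=accs[protein_of[i]],
            log_e=float(log_e[i]),
            has_label=bool(has_label[i]),
            in_target_db=bool(in_db[i]),
            intensities=tuple(intens[i]),
        )
        for i in range(n_spec)
    ]

    truth = GroundTruth(
        log2_fc=fc,
        ratios=ratios,
        expected_ratios=expected,
        de_direction=de_dir,
        norm_factors=norm_factors,
        pre_mix_intensities=pd.DataFrame(
            pre_mix, index=spectrum_ids, columns=[f"i{c}" for c in (114, 115, 116, 117)]
        ),
    )
    return records, truth


@dataclass(frozen=True)
class PlantedPathway:
    """A pathway to over-represent: ``proteins`` must land in a pathway of ``size`` members."""

    pathway_id: str
    proteins: frozenset[str]
    size: int


def generate_annotation(
    proteins: Sequence[str] | int,
    n_pathways: int = 20,
    planted: PlantedPathway | None = None,
    seed: int = 0,
) -> AnnotationMap:
    """Random COG letters and pathway memberships, optionally with one planted
    over-represented pathway.  Deterministic given ``seed``."""
    if isinstance(proteins, int):
        proteins = protein_ids(proteins)
    proteins = list(proteins)
    if n_pathways < 1:
        raise ConfigurationError("n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    pathway_names = [f"pw{i:03d}" for i in range(1, n_pathways + 1)]

    cog = {acc: str(rng.choice(COG_ALPHABET)) for acc in proteins}
    pathways: dict[str, set[str]] = {}
    for acc in proteins:
        k = int(rng.integers(1, min(3, n_pathways) + 1))
        chosen = rng.choice(n_pathways, size=k, replace=False)
        pathways[acc] = {pathway_names[i] for i in chosen}

    if planted is not None:
        members = set(planted.proteins)
        unknown = members - set(proteins)
        if unknown:
            raise ValidationError(f"planted proteins not in universe: {sorted(unknown)[:5]}")
        if planted.size < len(members):
            raise ValidationError(
                f"planted overlap {len(members)} exceeds pathway size {planted.size}"
            )
        if planted.size > len(proteins):
            raise ValidationError("planted pathway larger than the protein universe")
        others = sorted(set(proteins) - members)
        fill = rng.choice(len(others), size=planted.size - len(members), replace=False)
        for acc in members | {others[i] for i in fill}:
            pathways[acc] = pathways[acc] | {planted.pathway_id}

    return AnnotationMap(cog=cog, pathways={a: frozenset(p) for a, p in pathways.items()})
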