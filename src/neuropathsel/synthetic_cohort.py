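"""Synthetic post-mortem cohort generator.

The real cohort this package was designed around (a population-based
brain-donation study scored for Alzheimer-related and other
neuropathologies) is access-controlled, so every downstream stage is
exercised on synthetic tables that emulate its printed structure: 186
subjects (107 dementia / 70 no dementia / 9 with unknown status), 34
neuropathology features plus age, brain weight and sex, seven regional
"non-standard" pathology features, per-feature missingness, monotone
dementia gradients across staging levels, and three blocks of highly
correlated features (cerebral amyloid angiopathy, thorn-shaped
astrocytes, microinfarcts).

Generative model
----------------
Each subject carries a latent standard-Gaussian dementia liability
``L``.  Dementia status is assigned by ranking liabilities so the
configured class counts are hit exactly; the label-unknown subset is
drawn completely at random.  Each feature's latent score is

    z = effect_size * L + u,

where ``u`` is unit-variance noise; features sharing a block draw
``u = sqrt(lam) * B + sqrt(1 - lam) * eps`` from a shared per-block
factor ``B`` (``lam`` = ``block_loading``), which reproduces the
within-block rank correlations.  Ordinal and binary features are cut
from ``z`` at equal-probability thresholds; numeric features are an
affine map of ``z`` onto the stated range.  Missingness is injected
completely at random per feature.  Generation is a pure function of the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_prep import LABEL_COLUMN, CohortTable, FeatureSpec

__all__ = ["FeatureSpec", "CohortConfig", "default_cohort_schema", "generate_cohort"]

#: Non-standard regional pathology features plus demographics: the pool used
#: to explain misclassification clusters.
NONSTANDARD_FEATURES = [
    "age",
    "brain_weight",
    "gender",
    "virchow_robin_space_expansion",
    "lewy_bodies_substantia_nigra",
    "neuronal_loss_hippocampus",
    "neuronal_loss_substantia_nigra",
    "tangles_temporal_lobe",
    "parenchymal_caa_frontal_lobe",
    "gliosis_hippocampus",
]


@dataclass
class CohortConfig:
    """Cohort composition and generation parameters.

    Defaults reproduce the printed study composition: 186 subjects split
    107 dementia / 70 no dementia / 9 label-unknown.
    """

    n_total: int = 186
    n_dementia: int = 107
    n_nodementia: int = 70
    n_label_missing: int = 9
    features: list[FeatureSpec] = field(default_factory=lambda: default_cohort_schema())
    block_loading: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dementia + self.n_nodementia + self.n_label_missing != self.n_total:
            raise ValueError("label counts must sum to n_total")
        if not 0.0 < self.block_loading < 1.0:
            raise ValueError("block_loading must lie in (0, 1)")


def _ordinal(name, n_levels, missing_rate=0.0, effect=0.0, block=None):
    return FeatureSpec(name, "ordinal", list(range(n_levels)), missing_rate, effect, block)


def _binary(name, missing_rate=0.0, effect=0.0, block=None):
    return FeatureSpec(name, "nominal", [0, 1], missing_rate, effect, block)


def _numeric(name, lo, hi, missing_rate=0.0, effect=0.0, block=None):
    return FeatureSpec(name, "numeric", [lo, hi], missing_rate, effect, block)


def default_cohort_schema() -> list[FeatureSpec]:
    """The 45-entry default schema: 34 neuropathology features, age,
    brain weight, sex, seven regional non-standard features, and the
    dementia label.

    Staging schemes (Braak 0-VI, amyloid/Thal phases, BrainNet tau
    stages, severity scores) are ordinal integer codes; presence/absence
    features are 0/1; counts, summed severities, age and brain weight
    are numeric.  Missingness rates follow the printed per-feature
    missing fractions (of the 177 status-known subjects).  Tau-staging
    features carry large positive effects; the three correlated blocks
    carry moderate block-shared effects.
    """
    return [
        _ordinal("braak_nft_stage", 7, 0.0, 1.1),
        _ordinal("thal_phase", 6, 0.0, 0.95),
        _binary("abeta_stage_typical", 0.0, 0.25),
        _binary("part_definite", 0.452, 0.1),
        _binary("part_all", 0.243, 0.1),
        _numeric("caa_areas", 0, 9, 0.0, 0.5, "CAA"),
        _ordinal("caa_type", 3, 0.0, 0.5, "CAA"),
        _ordinal("caa_parenchymal", 13, 0.0, 0.5, "CAA"),
        _ordinal("caa_meningeal", 13, 0.0, 0.5, "CAA"),
        _numeric("caa_total_severity", 0, 24, 0.0, 0.5, "CAA"),
        _binary("caa_frontal", 0.0, 0.4, "CAA"),
        _binary("caa_temporal", 0.0, 0.4, "CAA"),
        _binary("caa_parietal", 0.0, 0.4, "CAA"),
        _binary("caa_occipital", 0.0, 0.4, "CAA"),
        _binary("caa_hippocampus", 0.0, 0.4, "CAA"),
        _binary("caa_cerebellum", 0.0113, 0.4, "CAA"),
        _ordinal("brainnet_tau_stage", 7, 0.006, 1.1),
        _ordinal("hippocampal_tau_nft_stage", 5, 0.48, 0.6),
        _binary("subpial_tsa_expanded_cortex", 0.006, 0.4, "TSA"),
        _binary("subpial_tsa_mesial_temporal", 0.006, 0.6, "TSA"),
        _binary("subpial_tsa_brainstem", 0.017, 0.4, "TSA"),
        _binary("tsa_any", 0.006, 0.4, "TSA"),
        _numeric("tsa_total", 0, 9, 0.006, 0.4, "TSA"),
        _binary("tufted_astrocytes", 0.006, 0.0),
        _binary("subpial_mesial_temporal", 0.006, 0.45),
        _binary("subpial_brainstem", 0.017, 0.45),
        _binary("argyrophilic_grains", 0.006, 0.1),
        _numeric("cortical_stage", 0, 9, 0.006, 0.3, "microinfarct"),
        _numeric("subcortical_stage", 0, 9, 0.006, 0.3, "microinfarct"),
        _numeric("microinfarct_stage", 0, 9, 0.006, 0.3, "microinfarct"),
        _binary("frontal_microinfarct", 0.006, 0.2, "microinfarct"),
        _binary("temporal_microinfarct", 0.006, 0.2, "microinfarct"),
        _binary("parietal_microinfarct", 0.006, 0.0, "microinfarct"),
        _binary("occipital_microinfarct", 0.006, 0.2, "microinfarct"),
        _numeric("age", 64, 105, 0.0, 0.5),
        _numeric("brain_weight", 850, 1550, 0.15, -0.5),
        _binary("gender", 0.0, 0.0),
        _binary("virchow_robin_space_expansion", 0.006, 0.3),
        _binary("lewy_bodies_substantia_nigra", 0.023, 0.4),
        _binary("neuronal_loss_hippocampus", 0.006, 0.45),
        _binary("neuronal_loss_substantia_nigra", 0.023, 0.4),
        _binary("tangles_temporal_lobe", 0.006, 0.55),
        _binary("parenchymal_caa_frontal_lobe", 0.006, 0.35),
        _binary("gliosis_hippocampus", 0.006, 0.45),
        FeatureSpec(LABEL_COLUMN, "binary_label", [0, 1], 0.0, 0.0, None),
    ]


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> CohortTable:
    """Generate a cohort table from ``config``.

    ``seed`` overrides ``config.seed`` when given.  The returned table
    has exactly the configured label counts for every seed and is
    bit-identical for identical seeds.
    """
    config = config or CohortConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_total

    liability = rng.standard_normal(n)

    # Label: unknown-status subjects drawn at random; among the rest, the
    # highest-liability subjects are the dementia cases (exact counts).
    label = np.full(n, np.nan)
    missing_idx = rng.choice(n, size=config.n_label_missing, replace=False)
    known = np.setdiff1d(np.arange(n), missing_idx)
    order = known[np.argsort(-liability[known], kind="stable")]
    label[order[: config.n_dementia]] = 1.0
    label[order[config.n_dementia :]] = 0.0

    blocks = sorted({s.block for s in config.features if s.block is not None})
    block_factor = {b: rng.standard_normal(n) for b in blocks}
    lam = config.block_loading

    columns: dict[str, np.ndarray] = {}
    for spec in config.features:
        if spec.kind == "binary_label":
            continue
        eps = rng.standard_normal(n)
        if spec.block is not None:
            u = np.sqrt(lam) * block_factor[spec.block] + np.sqrt(1.0 - lam) * eps
        else:
            u = eps
        z = spec.effect_size * liability + u
        sd = np.sqrt(spec.effect_size**2 + 1.0)

        if spec.kind in ("ordinal", "nominal"):
            k = len(spec.levels)
            cuts = stats.norm.ppf(np.arange(1, k) / k) * sd
            codes = np.searchsorted(cuts, z)
            values = np.asarray(spec.levels, dtype=float)[codes]
        else:  # numeric: affine map of z onto [lo, hi], +/-3 SD spans the range
            lo, hi = float(spec.levels[0]), float(spec.levels[1])
            centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
            values = np.round(np.clip(centre + z / sd * (half / 3.0), lo, hi))

        if spec.missing_rate > 0:
            mask = rng.random(n) < spec.missing_rate
            values = values.astype(float)
            values[mask] = np.nan
        columns[spec.name] = values

    columns[LABEL_COLUMN] = label
    index = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
    data = pd.DataFrame(columns, index=index)
    return CohortTable(data=data, feature_meta=list(config.features))
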