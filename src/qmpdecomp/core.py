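"""Shared containers and conventions for the pipeline.

Orientation convention, used everywhere: **taxa (or features) are rows,
samples are columns**.  Every TSV written by the package states this in its
provenance header.

Abundance modes
---------------
``raw_reads``
    Integer sequencing read counts, spike-in rows may still be present.
``copies_per_gram``
    Spike-in calibrated absolute abundance (QMP): gene copies per gram of
    sample input material.
``rarefied_reads``
    Reads subsampled without replacement to a common depth (the RMP basis).
``relative``
    Column-normalised proportions (each sample sums to 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("qmpdecomp")

ABUNDANCE_MODES = ("raw_reads", "copies_per_gram", "rarefied_reads", "relative")
SAMPLE_TYPES = ("regular_soil", "grave_soil", "tissue")
DOMAINS = ("bacteria", "fungi")

#: metadata columns required by the pipeline
METADATA_COLUMNS = ("sample_type", "day", "replicate", "mass_g")


@dataclass
class AbundanceMatrix:
    """A taxa x samples abundance table with a declared measurement mode."""

    data: pd.DataFrame
    mode: str
    domain: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ABUNDANCE_MODES:
            raise ValueError(f"unknown abundance mode {self.mode!r}; expected one of {ABUNDANCE_MODES}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be nonnegative")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate taxon IDs in abundance matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in abundance matrix")

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def with_data(self, data: pd.DataFrame, mode: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(data=data, mode=mode or self.mode, domain=self.domain)

    def relative(self) -> "AbundanceMatrix":
        """Column-normalise to proportions."""
        totals = self.data.sum(axis=0)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"cannot normalise samples with zero total: {bad}")
        return AbundanceMatrix(self.data / totals, mode="relative", domain=self.domain)


def check_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample metadata table (index = sample ID)."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if metadata.index.has_duplicates:
        raise ValueError("duplicate sample IDs in metadata")
    unknown = set(metadata["sample_type"]) - set(SAMPLE_TYPES)
    if unknown:
        raise ValueError(f"unknown sample types in metadata: {sorted(unknown)}")
    return metadata


def subseeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass
class GroundTruth:
    """Known truth behind a simulated cohort.

    ``loads`` maps domain -> taxa x samples matrix of true copies per gram.
    ``metabolite_trend_sign`` is +1/-1/0 per metabolite feature, and
    ``driver_map`` maps driven metabolite features to their (domain, taxon)
    driver.
    """

    metadata: pd.DataFrame
    loads: dict[str, pd.DataFrame]
    metabolite_trend_sign: pd.Series | None = None
    driver_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def total_load(self, domain: str) -> pd.Series:
        """True total copies per gram per sample for one domain."""
        return self.loads[domain].sum(axis=0)

    def __post_init__(self) -> None:
        check_metadata(self.metadata)
        for domain, mat in self.loads.items():
            if (mat.to_numpy() <= 0).any():
                raise ValueError(f"{domain}: true loads must be strictly positive")
            if not mat.columns.equals(self.metadata.index):
                raise ValueError(f"{domain}: load columns do not match metadata samples")
        if self.driver_map:
            taxa = {d: set(m.index) for d, m in self.loads.items()}
            for feat, (domain, taxon) in self.driver_map.items():
                if domain not in taxa or taxon not in taxa[domain]:
                    raise ValueError(f"driver map references unknown taxon {domain}/{taxon}")
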