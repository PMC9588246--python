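"""The assembled analysis table: samples x covariates plus a beta-value matrix.

Layout mirrors what a methylation-array study hands to its statisticians:
a sample sheet (one row per specimen, i.e. per participant-visit), a lipid
table in mmol/L, and a probes x samples matrix of beta-values in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LIPIDS

SAMPLE_COLUMNS = [
    "participant",
    "pair_id",
    "zygosity",
    "visit",
    "age",
    "sex",
    "smoking",
    "alcohol",
    "bmi",
    "fasting",
    "lipid_med",
    "batch",
]

VISITS = ("baseline", "followup")


@dataclass
class TwinCohort:
    """Sample sheet + lipid table + beta matrix, indexed by sample id.

    ``samples``: DataFrame indexed by sample id with :data:`SAMPLE_COLUMNS`
    plus one ``cell_*`` column per cell type (proportions in [0, 1]).
    ``lipids``: DataFrame indexed by sample id, columns TG/TC/HDL_C/LDL_C.
    ``beta``: DataFrame probes x samples.
    ``snp_beta``: optional DataFrame of SNP-overlapping probes x samples
    (baseline specimens), used for zygosity calling.
    """

    samples: pd.DataFrame
    lipids: pd.DataFrame
    beta: pd.DataFrame
    snp_beta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if not self.samples.index.equals(self.lipids.index):
            raise ValueError("sample sheet and lipid table indexes differ")
        if list(self.beta.columns) != list(self.samples.index):
            missing = set(self.samples.index).symmetric_difference(self.beta.columns)
            raise ValueError(f"beta columns do not match sample rows: {sorted(missing)[:5]} ...")
        sizes = self.samples.groupby(["pair_id", "visit"])["participant"].nunique()
        if (sizes > 2).any():
            bad = sizes[sizes > 2].index[0]
            raise ValueError(f"pair {bad} groups more than 2 participants")
        cells = self.cell_columns
        if cells:
            props = self.samples[cells].to_numpy()
            if (props < 0).any() or (props > 1).any():
                raise ValueError("cell proportions must lie in [0, 1]")

    @property
    def cell_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("cell_")]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_cpgs(self) -> int:
        return len(self.beta)

    def visit_mask(self, visit: str) -> pd.Series:
        return self.samples["visit"] == visit

    def subset(self, sample_ids) -> "TwinCohort":
        sample_ids = list(sample_ids)
        snp = None
        if self.snp_beta is not None:
            keep = [s for s in sample_ids if s in self.snp_beta.columns]
            snp = self.snp_beta[keep]
        return TwinCohort(
            samples=self.samples.loc[sample_ids].copy(),
            lipids=self.lipids.loc[sample_ids].copy(),
            beta=self.beta[sample_ids].copy(),
            snp_beta=snp,
        )

    def drop_probes(self, probes) -> "TwinCohort":
        return TwinCohort(
            samples=self.samples,
            lipids=self.lipids,
            beta=self.beta.drop(index=list(probes)),
            snp_beta=self.snp_beta,
        )

    # -- I/O ---------------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(path / "samples.tsv", sep="\t", index_label="sample_id")
        self.lipids.to_csv(path / "lipids.tsv", sep="\t", index_label="sample_id")
        self.beta.to_csv(path / "beta.tsv", sep="\t", index_label="probe")
        if self.snp_beta is not None:
            self.snp_beta.to_csv(path / "snp_beta.tsv", sep="\t", index_label="probe")

    @classmethod
    def from_dir(cls, path: str | Path) -> "TwinCohort":
        path = Path(path)
        samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col="sample_id")
        lipids = pd.read_csv(path / "lipids.tsv", sep="\t", index_col="sample_id")
        beta = pd.read_csv(path / "beta.tsv", sep="\t", index_col="probe")
        snp = None
        snp_path = path / "snp_beta.tsv"
        if snp_path.exists():
            snp = pd.read_csv(snp_path, sep="\t", index_col="probe")
        return cls(samples=samples, lipids=lipids[list(LIPIDS)], beta=beta, snp_beta=snp)
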