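"""In-memory containers shared across the pipeline.

Conventions: variant and gene coordinates are 1-based inclusive (BED tracks,
which are 0-based half-open, are converted at the I/O layer only); dosages are
counts of the alternate allele in [0, 2]; expression matrices are genes x
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: the normalisation stages, in the only order they may be applied
EXPRESSION_STAGES = ("tpm", "log", "qnorm", "rbint")


@dataclass
class GenotypeMatrix:
    """Per-sample allele dosages with variant and sample metadata.

    dosages: DataFrame, index = sample ids, columns = variant ids, values in [0, 2].
    variants: DataFrame indexed by variant id with columns
        ``chrom, pos, ref, alt`` and optionally ``imputation_r2``.
    samples: DataFrame indexed by sample id; covariate columns (age, sex, ...).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    samples: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.dosages.index)
        if not self.dosages.columns.equals(self.variants.index):
            self.variants = self.variants.loc[self.dosages.columns]
        vals = self.dosages.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.dosages.index.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.loc[ids], self.variants, self.samples.loc[ids]
        )

    def subset_variants(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[list(ids)], self.variants.loc[list(ids)], self.samples
        )

    def allele_freq(self) -> pd.Series:
        """Alternate-allele frequency per variant (ignores missing)."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)


@dataclass
class ExpressionMatrix:
    """Gene (or transcript) expression, genes x samples.

    ``stage`` tags where the matrix sits in the normalisation chain:
    tpm -> log -> qnorm -> rbint, transitions allowed only in that order.
    ``batch`` labels each sample's population/sequencing batch.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    stage: str = "tpm"
    batch: pd.Series = field(default=None)

    def __post_init__(self):
        if self.stage not in EXPRESSION_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.values.columns)
        else:
            self.batch = self.batch.reindex(self.values.columns)
        if not self.values.index.equals(self.genes.index):
            self.genes = self.genes.loc[self.values.index]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def advance_stage(self, new_values: pd.DataFrame, new_stage: str) -> "ExpressionMatrix":
        """Return a copy at ``new_stage``, enforcing the documented order."""
        if EXPRESSION_STAGES.index(new_stage) <= EXPRESSION_STAGES.index(self.stage):
            raise ValueError(
                f"stage transition {self.stage!r} -> {new_stage!r} is out of order"
            )
        out = replace(self, values=new_values, stage=new_stage)
        return out

    def subset_genes(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(ids)], self.genes.loc[list(ids)], self.stage, self.batch
        )

    def subset_samples(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(ids)], self.genes, self.stage, self.batch.loc[list(ids)]
        )
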