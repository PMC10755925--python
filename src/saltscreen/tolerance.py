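"""Salt-tolerance coefficient (STC) matrix.

Per accession and trait, the STC is the ratio of the trait's mean under
salt stress to its mean under control conditions.  Working on ratios
removes baseline (genetic) differences between accessions, so a low STC
means strong salt suppression of the trait regardless of the accession's
intrinsic size.  Replicates are averaged within treatment before the
ratio is taken: the ratio of means, not the mean of per-replicate
ratios, since dishes/pots are not paired across treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import TREATMENT_CONTROL, TREATMENT_SALT


@dataclass
class ToleranceMatrix:
    """Accessions x traits matrix of salt-tolerance coefficients.

    ``stc`` is a DataFrame with accession ids as the index and canonical
    trait names as columns.  ``provenance`` records the replicate count
    behind every cell mean, per treatment.
    """

    stc: pd.DataFrame
    provenance: pd.DataFrame  # columns: accession, trait, treatment, n

    @property
    def accessions(self) -> list[str]:
        return list(self.stc.index)

    @property
    def traits(self) -> list[str]:
        return list(self.stc.columns)

    def subset(self, traits: list[str]) -> "ToleranceMatrix":
        missing = [t for t in traits if t not in self.stc.columns]
        if missing:
            raise KeyError(f"traits not in matrix: {missing}")
        prov = self.provenance
        if "trait" in prov.columns:
            prov = prov[prov["trait"].isin(traits)].reset_index(drop=True)
        return ToleranceMatrix(self.stc[traits].copy(), prov)


def trait_means(obs: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per (accession, treatment, trait), with n.

    ``obs`` is a tidy observation table with columns accession,
    treatment, trait, replicate, value.
    """
    required = {"accession", "treatment", "trait", "value"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    grouped = (
        obs.groupby(["accession", "treatment", "trait"], sort=True)["value"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    return grouped


def compute_stc(means: pd.DataFrame, imputation: str = "error") -> ToleranceMatrix:
    """Build the STC matrix from per-cell treatment means.

    Every (accession, trait) cell needs both a control and a salt mean;
    a missing cell is a hard error under the default policy, or filled
    with the trait's mean STC under ``imputation='trait_mean'``.
    Control means must be strictly positive; salt means non-negative.
    """
    control = means[means["treatment"] == TREATMENT_CONTROL].pivot(
        index="accession", columns="trait", values="mean"
    )
    salt = means[means["treatment"] == TREATMENT_SALT].pivot(
        index="accession", columns="trait", values="mean"
    )
    accessions = sorted(set(control.index) | set(salt.index))
    traits = sorted(set(control.columns) | set(salt.columns))
    control = control.reindex(index=accessions, columns=traits)
    salt = salt.reindex(index=accessions, columns=traits)

    if (control.to_numpy() <= 0).any():  # NaN <= 0 is False; missing cells caught below
        bad = control.stack()[control.stack() <= 0]
        raise ValueError(f"non-positive control means (first: {bad.index[0]})")
    if (salt.to_numpy() < 0).any():
        raise ValueError("negative salt means encountered")

    stc = salt / control
    if stc.isna().to_numpy().any():
        if imputation == "error":
            r, c = np.where(stc.isna().to_numpy())
            missing = [(stc.index[i], stc.columns[j]) for i, j in zip(r, c)]
            raise ValueError(f"missing STC cells (first: {missing[0]}; {len(missing)} total)")
        # trait_mean: fill each trait column with its observed mean STC
        stc = stc.fillna(stc.mean(axis=0))
        if stc.isna().to_numpy().any():
            raise ValueError("imputation failed: a trait has no observed cells")

    prov = (
        means.groupby(["accession", "trait", "treatment"], sort=True)["n"]
        .sum()
        .reset_index()
    )
    return ToleranceMatrix(stc, prov)


def stc_from_observations(obs: pd.DataFrame, imputation: str = "error") -> ToleranceMatrix:
    """Convenience: replicate means then STC, in one call."""
    return compute_stc(trait_means(obs), imputation=imputation)
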