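"""Core in-memory containers shared across analysis stages.

Two containers carry essentially all data in the package:

``ExpressionExperiment``
    A log2 feature-by-sample matrix (microarray probes or RPPA epitopes)
    with per-sample metadata (cell line, treatment, replicate) and an
    optional probe-to-gene mapping.

``DoseResponsePanel``
    Long-format cytotoxicity fractions for a two-drug panel: three single
    doses of each drug plus a 3x3 combination grid per cell line, with
    replicates.  Cytotoxicity may be negative (net growth under drug).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("control", "treated")


class ValidationError(ValueError):
    """Raised when a container fails its structural invariants."""


@dataclass
class ExpressionExperiment:
    """Log2 expression values (features x samples) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature (probe/epitope) with one column per
        sample.
    samples
        DataFrame indexed by sample id with columns ``line``,
        ``treatment`` (``control`` or ``treated``) and ``replicate``.
    feature_to_gene
        Optional Series mapping feature id to gene symbol (many-to-one
        allowed).  When absent, features are taken to be genes.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    feature_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples metadata missing for columns: {sorted(missing)[:5]}")
        for col in ("line", "treatment", "replicate"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample metadata lacks required column {col!r}")
        bad = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment labels: {sorted(bad)}")
        meta = self.samples.loc[list(self.values.columns)]
        if meta.duplicated(subset=["line", "treatment", "replicate"]).any():
            raise ValidationError("duplicate (line, treatment, replicate) combination")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def lines(self) -> list[str]:
        return sorted(self.samples.loc[list(self.values.columns), "line"].unique())

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def subset(self, treatment: str) -> "ExpressionExperiment":
        meta = self.samples.loc[list(self.values.columns)]
        cols = meta.index[meta["treatment"] == treatment]
        return ExpressionExperiment(self.values[cols], self.samples.loc[cols], self.feature_to_gene)

    def basal(self) -> "ExpressionExperiment":
        """Control (untreated) samples only."""
        return self.subset("control")

    def line_means(self, treatment: str = "control") -> pd.DataFrame:
        """Features x lines matrix of replicate-averaged values."""
        meta = self.samples.loc[list(self.values.columns)]
        cols = meta.index[meta["treatment"] == treatment]
        grouping = meta.loc[cols, "line"]
        out = self.values[cols].T.groupby(grouping).mean().T
        return out.sort_index(axis=1)

    def paired_differences(self, lines: list[str] | None = None) -> pd.DataFrame:
        """Treated-minus-control differences matched on (line, replicate).

        Returns a features x pairs matrix with columns ``line:replicate``.
        Raises if any treated sample lacks a control partner (or vice
        versa) within the requested lines.
        """
        meta = self.samples.loc[list(self.values.columns)]
        if lines is not None:
            meta = meta[meta["line"].isin(lines)]
        key = list(zip(meta["line"], meta["replicate"]))
        by_key: dict[tuple, dict[str, str]] = {}
        for sample, k, trt in zip(meta.index, key, meta["treatment"]):
            by_key.setdefault(k, {})[trt] = sample
        diffs = {}
        for (line, rep), pair in sorted(by_key.items()):
            if set(pair) != set(TREATMENTS):
                have = next(iter(pair))
                raise ValidationError(
                    f"sample {pair[have]!r} ({have}) has no partner for line={line!r} replicate={rep!r}"
                )
            diffs[f"{line}:{rep}"] = self.values[pair["treated"]] - self.values[pair["control"]]
        return pd.DataFrame(diffs, index=self.values.index)


#: canonical column order of the long dose-response table
DOSE_COLUMNS = ["line", "dose_a", "dose_b", "replicate", "cytotoxicity"]


@dataclass
class DoseResponsePanel:
    """Cytotoxicity fractions for a two-drug dose panel in long format.

    ``data`` columns: ``line``, ``dose_a``, ``dose_b``, ``replicate``,
    ``cytotoxicity``.  Single-drug rows carry 0 for the other drug's dose.
    Drug A defaults to the BRaf inhibitor (PLX4720), drug B to the ErbB
    inhibitor (lapatinib).
    """

    data: pd.DataFrame
    drug_a: str = "PLX4720"
    drug_b: str = "lapatinib"

    def __post_init__(self) -> None:
        missing = set(DOSE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"dose-response table missing columns: {sorted(missing)}")
        if not np.isfinite(self.data["cytotoxicity"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite cytotoxicity values")

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    @property
    def doses_a(self) -> np.ndarray:
        d = self.data.loc[(self.data["dose_a"] > 0) & (self.data["dose_b"] == 0), "dose_a"]
        return np.sort(d.unique())

    @property
    def doses_b(self) -> np.ndarray:
        d = self.data.loc[(self.data["dose_b"] > 0) & (self.data["dose_a"] == 0), "dose_b"]
        return np.sort(d.unique())

    def _line_rows(self, line: str) -> pd.DataFrame:
        rows = self.data[self.data["line"] == line]
        if rows.empty:
            raise KeyError(f"unknown line {line!r}")
        return rows

    def single_means(self, line: str, drug: str) -> pd.Series:
        """Replicate-averaged single-drug cytotoxicity indexed by dose."""
        rows = self._line_rows(line)
        if drug == self.drug_a:
            sel = rows[(rows["dose_a"] > 0) & (rows["dose_b"] == 0)]
            out = sel.groupby("dose_a")["cytotoxicity"].mean()
        elif drug == self.drug_b:
            sel = rows[(rows["dose_b"] > 0) & (rows["dose_a"] == 0)]
            out = sel.groupby("dose_b")["cytotoxicity"].mean()
        else:
            raise KeyError(f"unknown drug {drug!r}")
        return out.sort_index()

    def combo_means(self, line: str) -> pd.DataFrame:
        """Replicate-averaged combination grid: rows doses of drug A, columns doses of drug B."""
        rows = self._line_rows(line)
        sel = rows[(rows["dose_a"] > 0) & (rows["dose_b"] > 0)]
        grid = sel.pivot_table(index="dose_a", columns="dose_b", values="cytotoxicity", aggfunc="mean")
        return grid.sort_index().sort_index(axis=1)

    def profile_matrix(self) -> pd.DataFrame:
        """Treatment-condition x cell-line matrix of replicate-averaged cytotoxicity.

        Conditions are the single doses of each drug plus every
        combination cell (15 rows for the standard 3+3+3x3 design).
        Raises if any line is missing any condition.
        """
        profiles = {}
        for line in self.lines:
            prof = {}
            for dose, val in self.single_means(line, self.drug_a).items():
                prof[f"{self.drug_a}@{dose:g}"] = val
            for dose, val in self.single_means(line, self.drug_b).items():
                prof[f"{self.drug_b}@{dose:g}"] = val
            grid = self.combo_means(line)
            for da in grid.index:
                for db in grid.columns:
                    prof[f"combo@{da:g}+{db:g}"] = grid.loc[da, db]
            profiles[line] = prof
        mat = pd.DataFrame(profiles)
        if mat.isna().any().any():
            bad = mat.columns[mat.isna().any()].tolist()
            raise ValidationError(f"incomplete dose grid for lines: {bad}")
        return mat
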