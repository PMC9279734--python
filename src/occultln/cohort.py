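"""Patient-level cohort containers and CSV input/output.

Two tabular shapes flow through the package:

* a *nodal cohort* — one row per patient with the number of lymph nodes
  examined pathologically (``nodes_examined``, the yield ``m``) and the
  number found positive (``nodes_positive``), plus optional clinical
  covariates; this is the substrate the beta-binomial model is fit to;
* a *survival cohort* — registry-style rows (histology, stage, treatment,
  follow-up, vital status) consumed by the survival verification pipeline.

Both are stored as plain :class:`pandas.DataFrame` objects; the thin
:class:`NodalCohort` wrapper adds validation and the per-yield summaries
the model needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Optional covariate columns accepted in nodal-cohort CSV files.
NODAL_COVARIATE_COLUMNS = (
    "age",
    "sex",
    "hashimoto",
    "clinical_n0",
    "surgery",
    "clnd_extent",
)

#: Hidden column carrying the simulated true nodal status (oracle only).
TRUE_STATUS_COLUMN = "_true_positive"

#: Columns of a survival-cohort table, in canonical order.
SURVIVAL_COLUMNS = (
    "patient_id",
    "histology_code",
    "tumor_size_mm",
    "n_stage",
    "m_stage",
    "prior_malignancy",
    "age_years",
    "sex",
    "race",
    "extrathyroidal_extension",
    "multifocality",
    "surgery_extent",
    "rai",
    "nodes_examined",
    "nodes_positive",
    "follow_up_months",
    "vital_status",
)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates its structural invariants."""


@dataclass
class NodalCohort:
    """Per-patient nodal pathology table.

    Parameters
    ----------
    table
        DataFrame with integer columns ``nodes_examined`` (>= 1) and
        ``nodes_positive`` (0 <= x <= m).  Extra columns are carried
        along untouched.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        for col in ("nodes_examined", "nodes_positive"):
            if col not in df.columns:
                raise CohortValidationError(f"missing required column {col!r}")
        m = df["nodes_examined"].to_numpy()
        x = df["nodes_positive"].to_numpy()
        if len(df) and (np.any(m < 1) or np.any(m != np.floor(m))):
            raise CohortValidationError("nodes_examined must be integers >= 1")
        if len(df) and (np.any(x < 0) or np.any(x > m)):
            raise CohortValidationError(
                "nodes_positive must satisfy 0 <= nodes_positive <= nodes_examined"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def nodes_examined(self) -> np.ndarray:
        return self.table["nodes_examined"].to_numpy(dtype=np.int64)

    @property
    def nodes_positive(self) -> np.ndarray:
        return self.table["nodes_positive"].to_numpy(dtype=np.int64)

    @property
    def n_node_positive(self) -> int:
        """Number of patients with at least one positive node (#TP)."""
        return int((self.nodes_positive >= 1).sum())

    @property
    def observed_prevalence(self) -> float:
        """Observed node-positive fraction #TP / N."""
        if len(self) == 0:
            raise CohortValidationError("empty cohort has no prevalence")
        return self.n_node_positive / len(self)

    def subset(self, mask: np.ndarray) -> "NodalCohort":
        return NodalCohort(self.table.loc[mask].reset_index(drop=True))

    def fitting_subset(
        self, min_nodes: int = 2, require_positive: bool = True
    ) -> "NodalCohort":
        """Restrict to the model-fitting substrate.

        The latent positivity law describes node-positive patients, so the
        default keeps patients with at least ``min_nodes`` examined and at
        least one positive node.
        """
        mask = self.nodes_examined >= min_nodes
        if require_positive:
            mask &= self.nodes_positive >= 1
        return self.subset(mask)

    def tp_counts_by_m(self) -> pd.Series:
        """#TP_m: node-positive patient count per yield m (m with #TP > 0)."""
        pos = self.table[self.table["nodes_positive"] >= 1]
        return pos.groupby("nodes_examined").size()

    def counts_by_m(self) -> pd.DataFrame:
        """Per-yield tallies: patients, node-positive (#TP), observed-negative."""
        g = self.table.groupby("nodes_examined")
        out = pd.DataFrame(
            {
                "n_patients": g.size(),
                "n_tp": g["nodes_positive"].apply(lambda s: int((s >= 1).sum())),
            }
        )
        out["n_observed_negative"] = out["n_patients"] - out["n_tp"]
        out.index.name = "m"
        return out

    def resample(self, rng: np.random.Generator) -> "NodalCohort":
        """Patient-level bootstrap resample of the same size."""
        idx = rng.integers(0, len(self), size=len(self))
        return NodalCohort(self.table.iloc[idx].reset_index(drop=True))


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surface the offending line
        raise CohortValidationError(f"malformed CSV {path}: {exc}") from exc


def read_nodal_csv(path, include_true_status: bool = False) -> NodalCohort:
    """Read a nodal cohort CSV (one row per patient, header mandatory).

    The hidden simulation column ``_true_positive`` is dropped unless
    ``include_true_status`` is set, so model-facing code never sees it.
    """
    df = _read_csv(path)
    if not include_true_status and TRUE_STATUS_COLUMN in df.columns:
        df = df.drop(columns=[TRUE_STATUS_COLUMN])
    return NodalCohort(df)


def write_nodal_csv(cohort: NodalCohort, path) -> None:
    cohort.table.to_csv(path, index=False)


def read_survival_csv(path) -> pd.DataFrame:
    """Read a survival cohort CSV, validating required fields."""
    df = _read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    bad = df["nodes_positive"] > df["nodes_examined"]
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based with header line
        raise CohortValidationError(
            f"nodes_positive > nodes_examined at line {row}"
        )
    if (df["follow_up_months"] < 0).any():
        raise CohortValidationError("follow_up_months must be >= 0")
    return df


def write_survival_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
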