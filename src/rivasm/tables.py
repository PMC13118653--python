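"""OTU count tables: containers, file I/O, filtering, normalization, rarefaction.

The central object is :class:`CommunityTable`, an integer OTU-by-sample
count matrix with aligned registries. Relative-abundance views produced by
:func:`tss_normalize` are plain ``pandas.DataFrame`` objects (OTUs as rows,
samples as columns, columns summing to 1).

On disk, tables are plain TSV with OTUs as rows by default (the common
amplicon convention); orientation can be forced or auto-detected from a
hint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rivasm._seeding import rng_for

__all__ = [
    "CommunityTable",
    "read_community_table",
    "write_community_table",
    "filter_otus",
    "tss_normalize",
    "rarefy",
    "read_metadata",
    "read_env_table",
    "read_taxonomy",
    "compute_din",
]


@dataclass
class CommunityTable:
    """Integer OTU x sample count matrix with aligned id registries.

    Parameters
    ----------
    counts : (n_otu, n_sample) ndarray of non-negative integers
    otu_ids : sequence of unique OTU identifiers (rows)
    sample_ids : sequence of unique sample identifiers (columns)
    """

    counts: np.ndarray
    otu_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.otu_ids = [str(x) for x in self.otu_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_otu, n_samp = self.counts.shape
        if len(self.otu_ids) != n_otu or len(self.sample_ids) != n_samp:
            raise ValueError("registry lengths do not match counts shape")
        if len(set(self.otu_ids)) != n_otu:
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            rounded = np.rint(as_int.astype(float))
            if not np.allclose(as_int.astype(float), rounded, atol=1e-9):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative counts are not allowed")

    # -- convenience -------------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts."""
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_samples(self, sample_ids) -> "CommunityTable":
        """Subset to the given samples (order preserved as given)."""
        idx = [self.sample_ids.index(str(s)) for s in sample_ids]
        return CommunityTable(self.counts[:, idx], self.otu_ids, [str(s) for s in sample_ids])

    def select_otus(self, otu_ids) -> "CommunityTable":
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[str(o)] for o in otu_ids]
        return CommunityTable(self.counts[idx], [str(o) for o in otu_ids], self.sample_ids)

    def drop_empty_otus(self) -> "CommunityTable":
        keep = self.counts.sum(axis=1) > 0
        return CommunityTable(
            self.counts[keep], [o for o, k in zip(self.otu_ids, keep) if k], self.sample_ids
        )


def read_community_table(path, orientation_hint: str = "auto", sep: str = "\t") -> CommunityTable:
    """Read a tab/comma-separated OTU table.

    ``orientation_hint`` is one of ``"taxa-as-rows"`` (default assumption),
    ``"samples-as-rows"``, or ``"auto"``. Auto-detection keeps taxa-as-rows
    unless the header looks like OTU identifiers (all header entries start
    with a shared OTU-style prefix while the index does not).
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"empty community table: {path}")
    if df.isna().any().any():
        raise ValueError("community table contains missing/ragged entries")
    if orientation_hint == "samples-as-rows":
        df = df.T
    elif orientation_hint == "auto":
        cols_otu = all(str(c).upper().startswith("OTU") for c in df.columns)
        rows_otu = all(str(r).upper().startswith("OTU") for r in df.index)
        if cols_otu and not rows_otu:
            df = df.T
    elif orientation_hint != "taxa-as-rows":
        raise ValueError(f"unknown orientation hint: {orientation_hint}")
    if df.index.duplicated().any():
        raise ValueError("duplicate OTU ids in table")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in table")
    values = df.to_numpy()
    try:
        numeric = values.astype(float)
    except ValueError as exc:
        raise ValueError("non-numeric entries in community table") from exc
    if (numeric < 0).any():
        raise ValueError("negative entries in community table")
    return CommunityTable(numeric, list(df.index), list(df.columns))


def write_community_table(table: CommunityTable, path, sep: str = "\t") -> None:
    df = table.to_dataframe()
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep=sep)


def filter_otus(
    table: CommunityTable,
    drop_singletons: bool = True,
    min_prevalence: float = 0.0,
):
    """Remove singleton OTUs (total count 1) and/or low-prevalence OTUs.

    Prevalence is the fraction of samples in which the OTU has a nonzero
    count; OTUs with prevalence strictly below ``min_prevalence`` are
    dropped. Returns ``(filtered_table, removed_ids)``.
    """
    totals = table.counts.sum(axis=1)
    prevalence = (table.counts > 0).mean(axis=1)
    keep = np.ones(table.n_otus, dtype=bool)
    if drop_singletons:
        keep &= totals != 1
    if min_prevalence > 0:
        keep &= prevalence >= min_prevalence
    # OTUs that vanished entirely (total 0) are always dropped
    keep &= totals > 0
    removed = [o for o, k in zip(table.otu_ids, keep) if not k]
    if not keep.any():
        raise ValueError("filtering removed all OTUs")
    kept = CommunityTable(
        table.counts[keep], [o for o, k in zip(table.otu_ids, keep) if k], table.sample_ids
    )
    return kept, removed


def tss_normalize(table) -> pd.DataFrame:
    """Total-sum scaling: divide each sample column by its total.

    Accepts a :class:`CommunityTable` or an OTU x sample DataFrame (already
    normalized input is returned unchanged up to float division, making the
    operation idempotent). Columns of the result sum to 1.
    """
    if isinstance(table, CommunityTable):
        df = table.to_dataframe().astype(float)
    else:
        df = pd.DataFrame(table).astype(float)
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    return df / totals


def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int,
    drop_undersampled: bool = False,
    method: str = "hypergeometric",
) -> CommunityTable:
    """Subsample each sample to a fixed depth.

    Default is sampling without replacement (multivariate hypergeometric),
    so an OTU's rarefied count never exceeds its original count and absent
    OTUs stay absent. A multinomial (with-replacement) variant is exposed
    for sensitivity analyses. Reproducible for a given seed; per-sample
    streams are keyed by sample id so results do not depend on column order.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    libs = table.library_sizes()
    low = libs[libs < depth]
    if len(low) > 0:
        if not drop_undersampled:
            raise ValueError(
                f"samples below rarefaction depth {depth}: {list(low.index)}"
            )
        table = table.select_samples([s for s in table.sample_ids if libs[s] >= depth])
    out = np.zeros_like(table.counts)
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rng = rng_for(seed, "rarefy", sid)
        if method == "hypergeometric":
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
        elif method == "multinomial":
            out[:, j] = rng.multinomial(depth, col / col.sum())
        else:
            raise ValueError(f"unknown rarefaction method: {method}")
    return CommunityTable(out, table.otu_ids, table.sample_ids)


# ---------------------------------------------------------------------------
# metadata / environment / taxonomy
# ---------------------------------------------------------------------------

def read_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Sample metadata: sample_id, season, reach, replicate."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "season", "reach", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    df = df.set_index("sample_id", drop=False)
    df["replicate"] = df["replicate"].astype(int)
    return df


DIN_COMPONENTS = ("NH4", "NO3", "NO2")


def read_env_table(path, sep: str = "\t") -> pd.DataFrame:
    """Environmental table keyed by (reach, season)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("reach", "season"):
        if col not in df.columns:
            raise ValueError(f"environmental table missing '{col}' column")
    return df


def compute_din(env: pd.DataFrame) -> pd.DataFrame:
    """Append dissolved inorganic nitrogen: DIN = NH4-N + NO3-N + NO2-N."""
    missing = [c for c in DIN_COMPONENTS if c not in env.columns]
    if missing:
        raise ValueError(f"cannot compute DIN; missing component(s): {missing}")
    out = env.copy()
    out["DIN"] = env["NH4"].astype(float) + env["NO3"].astype(float) + env["NO2"].astype(float)
    return out


RANKS = ("phylum", "class", "order", "family", "genus")


def read_taxonomy(path, sep: str = "\t") -> pd.DataFrame:
    """OTU -> ranked lineage. Accepts either one column per rank or a single
    semicolon-joined 'lineage' column (rank prefixes like 'p__' optional);
    unparsed ranks become 'unclassified'."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "otu_id" not in df.columns:
        raise ValueError("taxonomy table missing 'otu_id' column")
    df = df.set_index("otu_id")
    if "lineage" in df.columns:
        parsed = {r: [] for r in RANKS}
        for lin in df["lineage"].fillna(""):
            parts = [p.strip() for p in lin.split(";")]
            parts = [p.split("__", 1)[-1] if "__" in p else p for p in parts]
            for i, r in enumerate(RANKS):
                val = parts[i] if i < len(parts) and parts[i] else "unclassified"
                parsed[r].append(val)
        df = pd.DataFrame(parsed, index=df.index)
    for r in RANKS:
        if r not in df.columns:
            df[r] = "unclassified"
        df[r] = df[r].fillna("unclassified").replace("", "unclassified")
    return df[list(RANKS)]
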