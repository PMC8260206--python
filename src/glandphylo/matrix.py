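"""Read-count matrix of mutations across microdissections."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd


class VafMatrixError(ValueError):
    pass


class VafMatrix:
    """Alt/total read counts for every mutation x microdissection.

    Two aligned integer DataFrames (rows = mutation ids, columns =
    sample ids).  Depth 0 encodes a missing observation; ``0 <= alt <=
    depth`` holds everywhere.
    """

    def __init__(self, alt: pd.DataFrame, depth: pd.DataFrame):
        if not alt.index.equals(depth.index) or not alt.columns.equals(depth.columns):
            raise VafMatrixError("alt and depth must share index and columns")
        alt = alt.astype(np.int64)
        depth = depth.astype(np.int64)
        if (alt.to_numpy() < 0).any() or (depth.to_numpy() < 0).any():
            raise VafMatrixError("negative read counts")
        if (alt.to_numpy() > depth.to_numpy()).any():
            raise VafMatrixError("alt count exceeds depth")
        self.alt = alt
        self.depth = depth

    # -- basic queries ------------------------------------------------

    @property
    def mutations(self) -> list[str]:
        return list(self.alt.index)

    @property
    def samples(self) -> list[str]:
        return list(self.alt.columns)

    @property
    def n_mutations(self) -> int:
        return len(self.alt.index)

    @property
    def n_samples(self) -> int:
        return len(self.alt.columns)

    def vaf(self) -> pd.DataFrame:
        """alt/depth with NaN where depth is 0."""
        depth = self.depth.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(depth > 0, self.alt.to_numpy() / depth, np.nan)
        return pd.DataFrame(v, index=self.alt.index, columns=self.alt.columns)

    def subset(self, mutations=None, samples=None) -> "VafMatrix":
        alt, depth = self.alt, self.depth
        if mutations is not None:
            alt, depth = alt.loc[mutations], depth.loc[mutations]
        if samples is not None:
            alt, depth = alt[samples], depth[samples]
        return VafMatrix(alt, depth)

    def sort(self) -> "VafMatrix":
        """Canonical row/column order (lexicographic ids)."""
        alt = self.alt.sort_index().sort_index(axis=1)
        depth = self.depth.sort_index().sort_index(axis=1)
        return VafMatrix(alt, depth)

    def checksum(self) -> str:
        m = self.sort()
        h = hashlib.sha256()
        h.update("\t".join(m.samples).encode())
        h.update(m.alt.to_numpy().tobytes())
        h.update(m.depth.to_numpy().tobytes())
        h.update("\n".join(m.mutations).encode())
        return h.hexdigest()

    def __eq__(self, other) -> bool:
        if not isinstance(other, VafMatrix):
            return NotImplemented
        a, b = self.sort(), other.sort()
        return (
            a.alt.index.equals(b.alt.index)
            and a.alt.columns.equals(b.alt.columns)
            and (a.alt.to_numpy() == b.alt.to_numpy()).all()
            and (a.depth.to_numpy() == b.depth.to_numpy()).all()
        )

    # -- long-format interchange --------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long table (mutation_id, sample_id, alt_count, depth); rows
        with depth 0 are dropped."""
        alt = self.alt.stack()
        depth = self.depth.stack()
        df = pd.DataFrame({"alt_count": alt, "depth": depth}).reset_index()
        df.columns = ["mutation_id", "sample_id", "alt_count", "depth"]
        df = df[df["depth"] > 0].reset_index(drop=True)
        return df.sort_values(["mutation_id", "sample_id"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "VafMatrix":
        required = {"mutation_id", "sample_id", "alt_count", "depth"}
        missing = required - set(df.columns)
        if missing:
            raise VafMatrixError(f"missing columns: {sorted(missing)}")
        dup = df.duplicated(["mutation_id", "sample_id"])
        if dup.any():
            raise VafMatrixError(
                f"duplicate (mutation, sample) rows at indices {list(df.index[dup][:5])}"
            )
        bad = df["alt_count"] > df["depth"]
        if bad.any():
            raise VafMatrixError(
                f"alt_count exceeds depth at rows {list(df.index[bad][:5])}"
            )
        df = df.astype({"mutation_id": str, "sample_id": str})
        alt = df.pivot(index="mutation_id", columns="sample_id", values="alt_count")
        depth = df.pivot(index="mutation_id", columns="sample_id", values="depth")
        return cls(alt.fillna(0), depth.fillna(0)).sort()

    @classmethod
    def from_arrays(cls, alt, depth, mutations=None, samples=None) -> "VafMatrix":
        alt = np.asarray(alt)
        depth = np.asarray(depth)
        if mutations is None:
            mutations = [f"m{i}" for i in range(alt.shape[0])]
        if samples is None:
            samples = [f"s{j}" for j in range(alt.shape[1])]
        return cls(
            pd.DataFrame(alt, index=list(mutations), columns=list(samples)),
            pd.DataFrame(depth, index=list(mutations), columns=list(samples)),
        )
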