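"""Per-site read-count matrix shared by the simulator, the counters and the DMR caller."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SiteCountMatrix:
    """Non-negative read counts per LpnPI site (rows) per sample (columns).

    ``totals`` holds each sample's total filtered read count, which may exceed
    the column sum when reads map to no catalogued site; they are the
    denominators for RPM normalisation and for the chi-squared group totals.
    """

    site_ids: np.ndarray          # dense integer ids, catalogue order
    samples: list[str]
    counts: np.ndarray            # (n_sites, n_samples) int64
    totals: dict[str, int]        # per-sample total filtered reads
    groups: dict[str, str] = field(default_factory=dict)   # sample -> group label

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.site_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        missing = set(self.samples) - set(self.totals)
        if missing:
            raise ValueError(f"samples without totals: {sorted(missing)}")
        if self.groups:
            ungrouped = set(self.samples) - set(self.groups)
            if ungrouped:
                raise ValueError(f"samples without group label: {sorted(ungrouped)}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)]

    def pooled(self, samples: list[str]) -> tuple[np.ndarray, int]:
        """Pooled per-site counts and pooled total over a set of samples."""
        idx = [self.samples.index(s) for s in samples]
        return self.counts[:, idx].sum(axis=1), int(sum(self.totals[s] for s in samples))

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]

    # ---------------------------------------------------------------- I/O

    def to_frame(self, catalog=None) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "site_id", self.site_ids)
        if catalog is not None:
            sites = catalog.frame().set_index("site_id").loc[self.site_ids]
            df.insert(1, "chrom", sites["chrom"].to_numpy())
            df.insert(2, "pos", sites["pos"].to_numpy())
        return df

    def to_tsv(self, path: str | Path, catalog=None) -> None:
        """Write the matrix as TSV with a ``#total`` header line per sample."""
        path = Path(path)
        with path.open("w") as fh:
            for s in self.samples:
                group = self.groups.get(s, "")
                fh.write(f"#sample\t{s}\t{self.totals[s]}\t{group}\n")
            self.to_frame(catalog).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteCountMatrix":
        path = Path(path)
        totals: dict[str, int] = {}
        groups: dict[str, str] = {}
        header_lines = 0
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#sample\t"):
                    break
                _, sample, total, group = line.rstrip("\n").split("\t")
                totals[sample] = int(total)
                if group:
                    groups[sample] = group
                header_lines += 1
        df = pd.read_csv(path, sep="\t", skiprows=header_lines)
        meta = [c for c in ("site_id", "chrom", "pos") if c in df.columns]
        samples = [c for c in df.columns if c not in meta]
        return cls(
            site_ids=df["site_id"].to_numpy(),
            samples=samples,
            counts=df[samples].to_numpy(dtype=np.int64),
            totals=totals,
            groups=groups,
        )


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column sample/group TSV (no header) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], comment="#")
    return dict(zip(df["sample"], df["group"]))
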