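"""Input/output and coordinate plumbing for the windowed genome scan.

All internal coordinates are 0-based half-open. VCF (1-based) and GFF3
(1-based closed) are converted at the boundary, BED is consumed as is.
Genotypes are stored as *minor-allele* dosages, with the minor allele
defined once, globally across all samples, at load time, so that
per-population frequencies remain comparable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing diploid call

ECOTYPES = ("A", "R")
SEXES = ("F", "M", "unknown")


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class EmptyResultError(ValueError):
    """A filtering step removed every record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid minor-allele dosages for samples x biallelic SNP sites.

    ``sites`` has columns ``contig, pos, ref, alt`` with ``pos`` 0-based;
    positions are strictly increasing within a contig. ``calls`` is an
    ``int8`` array of shape (n_samples, n_sites) holding dosages in
    {0, 1, 2} of the globally-minor allele, or ``MISSING``.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        for contig, grp in self.sites.groupby("contig", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"positions not strictly increasing on {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise ValidationError(f"sample {e.args[0]!r} not in genotype matrix") from e

    def allele_stats(self, rows: np.ndarray | None = None):
        """Per-site (minor-allele count, non-missing chromosome count)."""
        calls = self.calls if rows is None else self.calls[rows]
        present = calls != MISSING
        counts = np.where(present, calls, 0).sum(axis=0)
        n_chrom = 2 * present.sum(axis=0)
        return counts.astype(np.int64), n_chrom.astype(np.int64)


@dataclass
class PopulationPanel:
    """Sample -> river / ecotype / sex assignments.

    Populations are identified as ``{river}_{ecotype}``; every river must
    carry both an anadromous (A) and a resident (R) population with at
    least two samples each.
    """

    table: pd.DataFrame  # columns: sample, river, ecotype, sex

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample", "river", "ecotype", "sex"}
        if not required.issubset(t.columns):
            raise FormatError(f"panel must have columns {sorted(required)}")
        if t["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in panel")
        bad = set(t["ecotype"]) - set(ECOTYPES)
        if bad:
            raise ValidationError(f"unknown ecotype codes: {sorted(bad)}")
        bad = set(t["sex"]) - set(SEXES)
        if bad:
            raise ValidationError(f"unknown sex codes: {sorted(bad)}")
        for river, grp in t.groupby("river", sort=False):
            for eco in ECOTYPES:
                n = (grp["ecotype"] == eco).sum()
                if n == 0:
                    raise ValidationError(f"river {river!r} lacks ecotype {eco}")
                if n < 2:
                    raise ValidationError(
                        f"population {river}_{eco} has {n} sample(s); >=2 required"
                    )

    @property
    def rivers(self) -> list[str]:
        return list(dict.fromkeys(self.table["river"]))

    @property
    def pop_ids(self) -> list[str]:
        """Deterministic population order: river order of the panel, A then R."""
        return [f"{river}_{eco}" for river in self.rivers for eco in ECOTYPES]

    def samples_of(self, river: str, ecotype: str) -> list[str]:
        t = self.table
        return list(t.loc[(t["river"] == river) & (t["ecotype"] == ecotype), "sample"])

    def samples_of_pop(self, pop_id: str) -> list[str]:
        river, eco = pop_id.rsplit("_", 1)
        return self.samples_of(river, eco)

    def samples_of_ecotype(self, ecotype: str) -> list[str]:
        t = self.table
        return list(t.loc[t["ecotype"] == ecotype, "sample"])

    def ecotype_of(self, pop_id: str) -> str:
        return pop_id.rsplit("_", 1)[1]

    def validate_against(self, G: GenotypeMatrix) -> None:
        missing = set(self.table["sample"]) - set(G.sample_ids)
        if missing:
            raise ValidationError(f"panel samples absent from genotypes: {sorted(missing)}")


@dataclass(frozen=True)
class WindowSpec:
    """One tile of the non-overlapping window grid (0-based half-open)."""

    contig: str
    start: int
    end: int
    callable_sites: int


@dataclass
class GeneAnnotation:
    gene_id: str
    contig: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotypes_vcf(
    path,
    panel: PopulationPanel | None = None,
    maf_min: float = 0.05,
    max_missing: float = 0.2,
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF as globally-minor-allele dosages.

    Sites are kept when the global minor-allele frequency (over non-missing
    calls) is >= ``maf_min`` and the non-missing call fraction is
    >= ``1 - max_missing``. Indels and multiallelic records are dropped.
    When a panel is given, samples are restricted to and ordered as the
    panel rows.
    """
    from cyvcf2 import VCF

    sample_subset = list(panel.table["sample"]) if panel is not None else None
    vcf = VCF(str(path), gts012=True, samples=sample_subset)
    if "GT" not in {f for f in _format_ids(vcf)}:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    if sample_subset is not None:
        absent = set(sample_subset) - set(samples)
        if absent:
            raise ValidationError(f"panel samples absent from VCF: {sorted(absent)}")

    contigs, positions, refs, alts = [], [], [], []
    dosage_rows = []
    min_present = 1.0 - max_missing
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        dos = np.where(gt == 3, MISSING, gt).astype(np.int8)
        present = dos != MISSING
        n_present = int(present.sum())
        if n_present == 0 or n_present / len(samples) < min_present:
            continue
        alt_count = int(dos[present].sum())
        n_chrom = 2 * n_present
        f_alt = alt_count / n_chrom
        if f_alt > 0.5:  # minor allele is REF: flip dosage
            dos = np.where(present, 2 - dos, MISSING).astype(np.int8)
            maf = 1.0 - f_alt
        else:
            maf = f_alt
        if maf < maf_min:
            continue
        contigs.append(v.CHROM)
        positions.append(v.POS - 1)  # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        dosage_rows.append(dos)
    vcf.close()
    if not dosage_rows:
        raise EmptyResultError(f"{path}: no sites survive filtering")
    sites = pd.DataFrame({"contig": contigs, "pos": positions, "ref": refs, "alt": alts})
    calls = np.stack(dosage_rows, axis=1)
    if sample_subset is not None and samples != sample_subset:
        order = [samples.index(s) for s in sample_subset]
        calls = calls[order]
        samples = sample_subset
    return GenotypeMatrix(sample_ids=samples, sites=sites, calls=calls)


def filter_by_maf(G: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Subset to sites with global minor-allele frequency >= ``maf_min``.

    Frequency-spectrum statistics are computed on all segregating sites to
    avoid biasing the spectrum; this filter builds the stricter SNP set
    used by the allele-frequency contrast.
    """
    counts, n_chrom = G.allele_stats()
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = counts / n_chrom  # dosages are already minor-allele counts
    keep = np.flatnonzero(maf >= maf_min)
    if keep.size == 0:
        raise EmptyResultError("no sites at or above the requested MAF")
    return GenotypeMatrix(
        sample_ids=G.sample_ids,
        sites=G.sites.iloc[keep].reset_index(drop=True),
        calls=np.ascontiguousarray(G.calls[:, keep]),
    )


def _format_ids(vcf):
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            yield line.split("ID=", 1)[1].split(",", 1)[0]


def make_windows(contig_lengths, mask, window_size: int = 10_000) -> list[WindowSpec]:
    """Tile each contig with non-overlapping windows and count callable bases.

    ``mask`` is a list of (contig, start, end) BED-style intervals; they
    must be sorted and non-overlapping within a contig and lie within the
    contig bounds. ``callable_sites`` of a window is the number of masked
    bases intersecting it.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for contig, start, end in mask:
        if contig not in contig_lengths:
            raise ValidationError(f"mask interval on unknown contig {contig!r}")
        if not (0 <= start < end <= contig_lengths[contig]):
            raise ValidationError(f"mask interval {contig}:{start}-{end} out of bounds")
        ivs = by_contig[contig]
        if ivs and start < ivs[-1][1]:
            raise ValidationError(f"mask intervals overlap or unsorted on {contig}")
        ivs.append((start, end))

    windows: list[WindowSpec] = []
    for contig, length in contig_lengths.items():
        ivs = by_contig[contig]
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        for wstart in range(0, length, window_size):
            wend = min(wstart + window_size, length)
            if len(starts):
                ov = np.minimum(ends, wend) - np.maximum(starts, wstart)
                callable_ = int(np.clip(ov, 0, None).sum())
            else:
                callable_ = 0
            windows.append(WindowSpec(contig, wstart, wend, callable_))
    return windows


def windows_frame(windows: list[WindowSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [w.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "callable_sites": [w.callable_sites for w in windows],
        }
    )


def assign_sites_to_windows(sites: pd.DataFrame, windows: list[pd.DataFrame] | pd.DataFrame) -> np.ndarray:
    """Window index (into the window list) for each site, -1 if none.

    Windows are half-open, so a site at ``pos == end`` belongs to the next
    window. Assumes the grid comes from :func:`make_windows` (regular tiling
    per contig in order).
    """
    wf = windows if isinstance(windows, pd.DataFrame) else windows_frame(windows)
    idx = np.full(len(sites), -1, dtype=np.int64)
    for contig, grp in wf.groupby("contig", sort=False):
        sel = sites["contig"].to_numpy() == contig
        if not sel.any():
            continue
        pos = sites.loc[sel, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        out = np.where(ok, grp.index.to_numpy()[np.clip(j, 0, len(ends) - 1)], -1)
        idx[sel] = out
    return idx


def read_panel(path) -> PopulationPanel:
    t = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample", "river", "ecotype", "sex"]
    if list(t.columns[:4]) != expected:
        raise FormatError(f"panel header must be {expected}, got {list(t.columns)}")
    t["sex"] = t["sex"].fillna("unknown")
    return PopulationPanel(t[expected])


def read_bed(path) -> list[tuple[str, int, int]]:
    t = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                    names=["contig", "start", "end"], dtype={0: str, 1: np.int64, 2: np.int64},
                    comment="#")
    return list(t.itertuples(index=False, name=None))


def read_gff(path) -> list[GeneAnnotation]:
    """Read gene features from a GFF3; 1-based closed -> 0-based half-open."""
    import pyranges

    df = pyranges.read_gff3(str(path), as_df=True)
    genes = df[df["Feature"] == "gene"]
    id_col = "ID" if "ID" in genes.columns else "gene_id"
    out = []
    seen = set()
    for row in genes.itertuples(index=False):
        gid = getattr(row, id_col)
        if gid in seen:
            raise ValidationError(f"duplicate gene id {gid!r}")
        seen.add(gid)
        # pyranges already converts GFF Start to 0-based.
        out.append(GeneAnnotation(gene_id=gid, contig=str(row.Chromosome),
                                  start=int(row.Start), end=int(row.End),
                                  strand=str(getattr(row, "Strand", "."))))
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.6g"


def write_track(records: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    """Write a TSV with deterministic column and row order."""
    df = records.copy()
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write contig/start/end (+extra columns) as headerless BED."""
    intervals.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FORMAT)
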