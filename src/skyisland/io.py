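"""Readers and writers for the pipeline's plain-text formats.

Formats: FASTA (60-column wrapped, via Biopython), Genepop 4-digit allele
codes, individual->population CSV maps, ESRI ASCII grids, labelled pairwise
matrices as CSV with a statistic-name header comment, and a flat key=value
configuration format.

Coordinate convention: raster indices are 0-based (row, col) with row 0 the
northern edge; site coordinates are projected metres.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .landscape import RasterGrid
from .popgen import MISSING, GenotypeMatrix, PairwiseMatrix, PopulationMap, SequenceAlignment

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genepop",
    "write_genepop",
    "read_popmap",
    "write_popmap",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_config",
    "write_config",
    "fetch_genbank_fasta",
]


def accession_range(first: str, last: str) -> list[str]:
    """Expand an accession range like MW166383..MW166433 inclusively."""
    prefix = first.rstrip("0123456789")
    if last.rstrip("0123456789") != prefix:
        raise ValueError("accession prefixes differ")
    lo = int(first[len(prefix):])
    hi = int(last[len(prefix):])
    width = len(first) - len(prefix)
    return [f"{prefix}{i:0{width}d}" for i in range(lo, hi + 1)]


def fetch_genbank_fasta(accessions: list[str], email: str, timeout: float = 30.0
                        ) -> SequenceAlignment:
    """Download nucleotide records from GenBank as a SequenceAlignment.

    Requires network access to NCBI; sequences must come back equal-length
    (already-aligned deposits) or a ValueError is raised.
    """
    import socket

    from Bio import Entrez

    Entrez.email = email
    old = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        handle = Entrez.efetch(db="nucleotide", id=",".join(accessions),
                               rettype="fasta", retmode="text")
        records = list(SeqIO.parse(handle, "fasta"))
        handle.close()
    finally:
        socket.setdefaulttimeout(old)
    if len(records) != len(accessions):
        raise ValueError(f"fetched {len(records)} of {len(accessions)} records")
    return SequenceAlignment([r.id for r in records],
                             [str(r.seq).upper() for r in records])


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path, partitions: dict[str, tuple[int, int]] | None = None
               ) -> SequenceAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceAlignment(
        [r.id for r in records],
        [str(r.seq).upper() for r in records],
        partitions or {},
    )


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # Biopython wraps at 60 columns


# -- Genepop ----------------------------------------------------------------


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, PopulationMap]:
    """Parse a Genepop file in the 4-digit allele-code dialect.

    The code ``0000`` denotes a missing allele; ``Pop`` lines delimit
    populations, which are named ``pop1 .. popK`` unless every individual id
    carries an explicit label.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("genepop file too short")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' line found")
    ids: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    pops: list[str] = []
    pop_idx = 0
    for lineno, line in enumerate(lines[i:], start=i + 1):
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in s:
            raise ValueError(f"line {lineno}: expected 'id , genotypes'")
        ind, geno = s.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"line {lineno}: {len(codes)} genotypes for {len(loci)} loci"
            )
        row = []
        for c in codes:
            if len(c) != 8 or not c.isdigit():
                raise ValueError(f"line {lineno}: bad 4-digit allele code {c!r}")
            a, b = int(c[:4]), int(c[4:])
            row.append((a if a else MISSING, b if b else MISSING))
        ids.append(ind.strip())
        calls.append(row)
        pops.append(f"pop{pop_idx}")
    arr = np.array(calls, dtype=np.int64)
    # normalize half-missing to fully missing
    half = (arr == MISSING).any(axis=2)
    arr[half] = MISSING
    gm = GenotypeMatrix(ids, loci, arr)
    return gm, PopulationMap(zip(ids, pops))


def write_genepop(gt: GenotypeMatrix, popmap: PopulationMap, path: str | Path,
                  title: str = "skyisland export") -> None:
    popmap.require_complete(gt.ids)
    out = [title]
    out.extend(gt.loci)
    current = None
    for idx, ind in enumerate(gt.ids):
        pop = popmap[ind]
        if pop != current:
            out.append("Pop")
            current = pop
        codes = []
        for a, b in gt.calls[idx]:
            a = 0 if a == MISSING else int(a)
            b = 0 if b == MISSING else int(b)
            if a > 9999 or b > 9999:
                raise ValueError("allele size exceeds 4-digit genepop code")
            codes.append(f"{a:04d}{b:04d}")
        out.append(f"{ind} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# -- population map ---------------------------------------------------------


def read_popmap(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("popmap CSV needs columns individual,population")
    return PopulationMap(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    pd.DataFrame(
        {"individual": list(popmap), "population": [popmap[i] for i in popmap]}
    ).to_csv(path, index=False)


# -- ESRI ASCII grid --------------------------------------------------------

_HEADER_KEYS = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value"]


def read_ascii_grid(path: str | Path) -> RasterGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0]] = float(parts[1])
            else:
                fh.seek(pos)
                break
        keys = {k.lower(): v for k, v in header.items()}
        for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if req not in keys:
                raise ValueError(f"{path}: missing header field {req!r}")
        values = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(keys["nrows"]), int(keys["ncols"])
    values = np.asarray(values, dtype=float).reshape(nrows, ncols)
    nodata = keys.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return RasterGrid(
        values=values,
        cellsize=keys["cellsize"],
        xllcorner=keys["xllcorner"],
        yllcorner=keys["yllcorner"],
        nodata_value=nodata if nodata is not None else -9999.0,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_ascii_grid(grid: RasterGrid, path: str | Path, fmt: str = "%.10g") -> None:
    buf = _io.StringIO()
    buf.write(f"ncols {grid.ncols}\n")
    buf.write(f"nrows {grid.nrows}\n")
    buf.write(f"xllcorner {grid.xllcorner:.10g}\n")
    buf.write(f"yllcorner {grid.yllcorner:.10g}\n")
    buf.write(f"cellsize {grid.cellsize:.10g}\n")
    buf.write(f"NODATA_value {grid.nodata_value:.10g}\n")
    vals = np.where(np.isnan(grid.values), grid.nodata_value, grid.values)
    np.savetxt(buf, vals, fmt=fmt)
    Path(path).write_text(buf.getvalue())


# -- pairwise matrix CSV ----------------------------------------------------


def write_matrix_csv(mat: PairwiseMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# statistic: {mat.name}\n")
        mat.to_frame().to_csv(fh)


def read_matrix_csv(path: str | Path) -> PairwiseMatrix:
    name = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# statistic:"):
            name = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, index_col=0)
    return PairwiseMatrix(list(df.index.astype(str)), df.to_numpy(float), name)


# -- key=value config -------------------------------------------------------


def read_config(path: str | Path, known_keys: set[str] | None = None) -> dict[str, str]:
    """Flat ``key = value`` config; ``#`` comments; unknown keys rejected
    when ``known_keys`` is given."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.split("#", 1)[0].strip()
        if not s:
            continue
        if "=" not in s:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        k, v = (x.strip() for x in s.split("=", 1))
        if known_keys is not None and k not in known_keys:
            raise ValueError(f"{path}:{lineno}: unknown config key {k!r}")
        out[k] = v
    return out


def write_config(cfg: dict[str, object], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in cfg.items()))
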