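"""File formats: genotype tables, phase tables, event BED, VCF, FASTA.

Conventions: positions are 0-based half-open internally and in BED; genotype
and phase TSVs and VCF are 1-based.  The genotype TSV dialect is a header row
of drone identifiers followed by one row per site — chrom, pos, ref, then one
allele per drone with ``.`` for missing calls and ``H`` for artifactual
heterozygous calls; colony membership travels in ``##colony`` header lines.
The dialect matches the shape of publicly posted drone genotype tables, which
carry genotypes only: depth, quality and strand flags are filled with
permissive defaults on read and quality-dependent filters then reduce to
call-rate filters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import CODE_HET, CODE_MISSING, GenotypeMatrix
from .phasing import QueenPhase
from .simulate import BASE_CHARS

_TSV_DEFAULT_DEPTH = 99
_TSV_DEFAULT_QUAL = 99.0


# ---------------------------------------------------------------------------
# Genotype TSV
# ---------------------------------------------------------------------------


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for d in matrix.drones:
            fh.write(f"##colony\t{d}\t{matrix.colonies[d]}\n")
        fh.write("chrom\tpos\tref\t" + "\t".join(matrix.drones) + "\n")
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            cells = [matrix.allele_string(i, int(c)) for c in matrix.calls[i]]
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.ref}\t"
                     + "\t".join(cells) + "\n")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    colonies: dict[str, str] = {}
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("##colony"):
                _, drone, colony = line.rstrip("\n").split("\t")
                colonies[drone] = colony
                header_lines += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype=str)
    drones = list(df.columns[3:])
    if not colonies:
        colonies = {d: d.split("-")[0] if "-" in d else "I" for d in drones}
    sites = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"].astype(np.int64) - 1,
        "ref": df["ref"],
    })
    n_sites, n_drones = len(sites), len(drones)
    calls = np.full((n_sites, n_drones), CODE_MISSING, dtype=np.int16)
    alleles: list[tuple[str, ...]] = []
    cell_matrix = df[drones].to_numpy(dtype=str)
    for i in range(n_sites):
        site_alleles = [sites["ref"].iat[i]]
        for j in range(n_drones):
            cell = cell_matrix[i, j]
            if cell == ".":
                calls[i, j] = CODE_MISSING
            elif cell == "H":
                calls[i, j] = CODE_HET
            else:
                if cell not in site_alleles:
                    site_alleles.append(cell)
                calls[i, j] = site_alleles.index(cell)
        alleles.append(tuple(site_alleles))
    shape = (n_sites, n_drones)
    return GenotypeMatrix(
        sites=sites, alleles=alleles, drones=drones, colonies=colonies,
        calls=calls,
        depth=np.full(shape, _TSV_DEFAULT_DEPTH, dtype=np.int32),
        quality=np.full(shape, _TSV_DEFAULT_QUAL, dtype=np.float32),
        strand_fwd=np.zeros(shape, dtype=bool),
        strand_rev=np.zeros(shape, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Phase tables
# ---------------------------------------------------------------------------


def write_phase_tsv(phase: QueenPhase, path: str | Path) -> None:
    t = phase.table
    out = pd.DataFrame({
        "chrom": t["chrom"], "pos": t["pos"] + 1,
        "hap0": t["hap0"], "hap1": t["hap1"], "phase_set": t["phase_set"],
    })
    with Path(path).open("w") as fh:
        fh.write(f"##colony\t{phase.colony}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_phase_tsv(path: str | Path) -> pd.DataFrame:
    """Read a phase table back as a DataFrame (0-based positions).

    The file stores alleles, not matrix codes; use :func:`reattach_phase` to
    rebuild a :class:`~dronehap.phasing.QueenPhase` against a matrix.
    """
    path = Path(path)
    colony = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("##colony"):
            colony = first.rstrip("\n").split("\t")[1]
    df = pd.read_csv(path, sep="\t", skiprows=1 if colony else 0)
    df["pos"] = df["pos"].astype(np.int64) - 1
    df.attrs["colony"] = colony
    return df


def reattach_phase(df: pd.DataFrame, matrix: GenotypeMatrix,
                   colony: str | None = None) -> QueenPhase:
    """Rebuild a QueenPhase (with matrix codes) from a read phase table."""
    colony = colony or df.attrs.get("colony")
    if colony is None:
        raise InputError("colony label required to reattach a phase table")
    key = {(c, p): i for i, (c, p) in
           enumerate(zip(matrix.sites["chrom"], matrix.sites["pos"]))}
    rows = []
    for _, r in df.iterrows():
        i = key.get((r["chrom"], int(r["pos"])))
        if i is None:
            raise InputError(f"phase marker {r['chrom']}:{r['pos']} not in matrix")
        al = matrix.alleles[i]
        try:
            code0, code1 = al.index(r["hap0"]), al.index(r["hap1"])
        except ValueError:
            raise InputError(
                f"phase alleles at {r['chrom']}:{r['pos']} not in matrix") from None
        rows.append((i, r["chrom"], int(r["pos"]), r["hap0"], r["hap1"],
                     code0, code1, int(r["phase_set"])))
    table = pd.DataFrame(rows, columns=["site_idx", "chrom", "pos", "hap0",
                                        "hap1", "code0", "code1", "phase_set"])
    return QueenPhase(colony=colony, table=table)


# ---------------------------------------------------------------------------
# Event BED
# ---------------------------------------------------------------------------

_BED_EXTRA = ["drone", "phase_set", "kind", "left", "right", "tract_start",
              "tract_end", "n_converted", "shared_group", "category",
              "excluded", "reason", "gap_overlap"]
_BED_NUMERIC = ("left", "right", "tract_start", "tract_end")


def write_events_bed(events: pd.DataFrame, path: str | Path) -> None:
    """Events as BED: the 0-based half-open interval is the breakpoint
    interval for crossovers and the converted tract for conversion events;
    all event fields travel in extra columns for lossless round trips."""
    with Path(path).open("w") as fh:
        fh.write("#chrom\tstart\tend\t" + "\t".join(_BED_EXTRA) + "\n")
        for _, e in events.iterrows():
            if e["kind"] == "CO":
                start, end = int(e["left"]), int(e["right"])
            else:
                start, end = int(e["tract_start"]), int(e["tract_end"])
            extras = []
            for col in _BED_EXTRA:
                v = e[col]
                if col in _BED_NUMERIC:
                    v = int(v) if np.isfinite(v) else "."
                elif col == "reason":
                    v = v if v else "."
                extras.append(str(v))
            fh.write(f"{e['chrom']}\t{start}\t{end}\t" + "\t".join(extras) + "\n")


def read_events_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"reason": str})
    df = df.rename(columns={"#chrom": "chrom"}).drop(columns=["start", "end"])
    for col in _BED_NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["reason"] = df["reason"].replace(".", "").fillna("")
    for col in ("excluded", "gap_overlap"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    from .recombination import EVENT_COLUMNS
    return df[[c for c in EVENT_COLUMNS if c in df.columns]]


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed_intervals(intervals, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(reference: dict[str, np.ndarray], path: str | Path,
                width: int = 80) -> None:
    """Write uint8-coded sequences (A=0..T=3, N=4) as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq("".join(BASE_CHARS[seq])), id=chrom, description="")
               for chrom, seq in reference.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    from Bio.SeqIO import parse as seqio_parse

    lookup = np.full(256, 4, dtype=np.uint8)
    for code, char in enumerate("ACGT"):
        lookup[ord(char)] = code
        lookup[ord(char.lower())] = code
    out = {}
    for rec in seqio_parse(str(path), "fasta"):
        raw = np.frombuffer(str(rec.seq).encode(), dtype=np.uint8)
        out[rec.id] = lookup[raw]
    return out


# ---------------------------------------------------------------------------
# VCF (pysam)
# ---------------------------------------------------------------------------


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a haploid multi-sample VCF (GT, DP, GQ, strand flags SF/SR)."""
    import pysam

    header = pysam.VariantHeader()
    lengths = chrom_lengths or {}
    for chrom in pd.unique(matrix.sites["chrom"]):
        length = lengths.get(chrom, int(matrix.sites.loc[
            matrix.sites["chrom"] == chrom, "pos"].max()) + 2)
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("SF", 1, "Integer", "Forward-strand support (0/1)")
    header.formats.add("SR", 1, "Integer", "Reverse-strand support (0/1)")
    for d, c in matrix.colonies.items():
        if d in matrix.drones:
            header.add_meta("colony", f"{d}={c}")
    for d in matrix.drones:
        header.add_sample(d)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            alts = tuple(a for a in matrix.alleles[i][1:])
            rec = vf.new_record(
                contig=row.chrom, start=int(row.pos),
                alleles=(matrix.alleles[i][0],) + (alts if alts else ("<NON_REF>",)),
            )
            for j, d in enumerate(matrix.drones):
                code = int(matrix.calls[i, j])
                sample = rec.samples[d]
                if code == CODE_MISSING:
                    sample["GT"] = (None,)
                elif code == CODE_HET:
                    sample["GT"] = (0, 1)
                else:
                    sample["GT"] = (code,)
                sample["DP"] = int(matrix.depth[i, j])
                sample["GQ"] = int(round(float(matrix.quality[i, j])))
                sample["SF"] = int(matrix.strand_fwd[i, j])
                sample["SR"] = int(matrix.strand_rev[i, j])
            vf.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a haploid multi-sample VCF into a GenotypeMatrix.

    Haploid GT fields give allele codes; diploid heterozygous GTs become the
    artifact code; DP/GQ populate depth and quality; SF/SR strand flags are
    honoured when present and left False (strand unknown) otherwise.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        drones = list(vf.header.samples)
        colonies = {}
        for rec_meta in vf.header.records:
            if rec_meta.key == "colony":
                d, c = str(rec_meta.value).split("=")
                colonies[d] = c
        if not colonies:
            colonies = {d: d.split("-")[0] if "-" in d else "I" for d in drones}
        sites_rows, alleles = [], []
        calls_rows, depth_rows, qual_rows, sf_rows, sr_rows = [], [], [], [], []
        for rec in vf:
            sites_rows.append((rec.contig, rec.start, rec.ref))
            alts = tuple(a for a in (rec.alts or ()) if a != "<NON_REF>")
            alleles.append((rec.ref,) + alts)
            calls, dps, gqs, sfs, srs = [], [], [], [], []
            for d in drones:
                s = rec.samples[d]
                gt = s.get("GT")
                if gt is None or gt == (None,) or all(g is None for g in gt):
                    calls.append(CODE_MISSING)
                elif len([g for g in gt if g is not None]) > 1 and len(set(gt)) > 1:
                    calls.append(CODE_HET)
                else:
                    calls.append(int([g for g in gt if g is not None][0]))
                dps.append(int(s.get("DP") or 0))
                gqs.append(float(s.get("GQ") if s.get("GQ") is not None
                                 else _TSV_DEFAULT_QUAL))
                sfs.append(bool(s.get("SF") or 0))
                srs.append(bool(s.get("SR") or 0))
            calls_rows.append(calls)
            depth_rows.append(dps)
            qual_rows.append(gqs)
            sf_rows.append(sfs)
            sr_rows.append(srs)
    sites = pd.DataFrame(sites_rows, columns=["chrom", "pos", "ref"])
    return GenotypeMatrix(
        sites=sites, alleles=alleles, drones=drones, colonies=colonies,
        calls=np.asarray(calls_rows, dtype=np.int16),
        depth=np.asarray(depth_rows, dtype=np.int32),
        quality=np.asarray(qual_rows, dtype=np.float32),
        strand_fwd=np.asarray(sf_rows, dtype=bool),
        strand_rev=np.asarray(sr_rows, dtype=bool),
    )


def write_mutations_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    """Mutation calls as a human-readable report (1-based positions)."""
    with Path(path).open("w") as fh:
        fh.write("number\tsample\tposition\ttype\tkind\n")
        for n, (_, c) in enumerate(calls.iterrows(), start=1):
            if c["kind"] == "SNM":
                typ = f"{c['ref']}->{c['alt']}"
            elif len(c["ref"]) > len(c["alt"]):
                typ = f"\"{c['ref'][1:]}\" deletion"
            else:
                typ = f"\"{c['alt'][1:]}\" insertion"
            fh.write(f"{n}\t{c['drone']}\t{c['chrom']}:{c['pos'] + 1}\t"
                     f"{typ}\t{c['kind']}\n")


# ---------------------------------------------------------------------------
# Callable counts, gene annotation, config
# ---------------------------------------------------------------------------


def write_callable_tsv(mask, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"##genome_length\t{mask.genome_length}\n")
        fh.write(f"##min_depth\t{mask.min_depth}\n")
        fh.write(f"##min_quality\t{mask.min_quality}\n")
        fh.write("drone\tcallable_sites\n")
        for d, v in mask.per_drone.items():
            fh.write(f"{d}\t{int(v)}\n")


def read_callable_tsv(path: str | Path):
    from .mutations import CallabilityMask

    meta = {}
    with Path(path).open() as fh:
        lines = fh.readlines()
    n_meta = 0
    for line in lines:
        if line.startswith("##"):
            k, v = line[2:].rstrip("\n").split("\t")
            meta[k] = float(v)
            n_meta += 1
        else:
            break
    df = pd.read_csv(Path(path), sep="\t", skiprows=n_meta)
    return CallabilityMask(
        per_drone=pd.Series(df["callable_sites"].to_numpy(),
                            index=df["drone"].tolist()),
        genome_length=int(meta.get("genome_length", df["callable_sites"].max())),
        min_depth=int(meta.get("min_depth", 5)),
        min_quality=float(meta.get("min_quality", 20.0)),
    )


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Gene intervals (chrom, start, end) from a GFF3 file."""
    import pyranges as pr

    gr = pr.read_gff3(str(path)).df
    genes = gr[gr["Feature"] == "gene"]
    return pd.DataFrame({"chrom": genes["Chromosome"].astype(str),
                         "start": genes["Start"].astype(int),
                         "end": genes["End"].astype(int)}).reset_index(drop=True)


def load_config_toml(path: str | Path) -> dict:
    import tomllib

    with Path(path).open("rb") as fh:
        return tomllib.load(fh)


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, stable float repr)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with Path(path).open("w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2, default=default)
        fh.write("\n")
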