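"""File-format plumbing: FASTA, VCF 4.2, BED depth tracks, TSV tables.

VCF records carry FORMAT fields GT, DP, AD, GQ and the INFO field SOR, the
annotations the filter chain consumes.  Coordinates are 1-based inclusive in
VCF and the pool table, 0-based half-open in BED, matching the respective
conventions.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnmcall import PoolSite, VariantCall

POOL_COLUMNS = [
    "scaffold", "pos_1based", "depth",
    "countA", "countC", "countG", "countT", "ins_count", "del_count",
]


def write_fasta(path: str | Path, genome) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.scaffolds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path):
    from .simdata import Genome

    scaffolds = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return Genome(scaffolds=scaffolds)


def write_vcf(path: str | Path, calls: Sequence[VariantCall], genome,
              sample: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SOR,Number=1,Type=Float,'
                 'Description="Symmetric odds ratio of strand bias">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        for name, seq in genome.scaffolds.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for c in sorted(calls, key=lambda c: (c.scaffold, c.pos, c.alt)):
            gt = "1/1" if c.genotype == "hom_alt" else "0/1"
            ref_n = (c.dp or 0) - (c.alt_count or 0)
            fh.write(
                f"{c.scaffold}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"SOR={c.sor:g}\tGT:DP:AD:GQ\t"
                f"{gt}:{c.dp}:{ref_n},{c.alt_count}:{int(c.gq)}\n"
            )


def read_vcf(path: str | Path, line_id: str) -> list[VariantCall]:
    """Read a VCF into per-alt :class:`VariantCall` records via pysam."""
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            sor = rec.info.get("SOR")
            for sample in samples or [None]:
                fmt = rec.samples[sample] if sample is not None else {}
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                gq = fmt.get("GQ")
                gt = fmt.get("GT", ())
                for ai, alt in enumerate(rec.alts or ()):
                    alt_count = ad[ai + 1] if ad is not None else None
                    genotype = "hom_alt" if gt and all(
                        g == ai + 1 for g in gt if g is not None
                    ) else "het"
                    calls.append(VariantCall(
                        line_id=line_id,
                        scaffold=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gq=float(gq) if gq is not None else None,
                        # INFO floats come back as float32; SOR is written
                        # with <= 3 decimals, so rounding restores it
                        sor=round(float(sor), 4) if sor is not None else None,
                        dp=int(dp) if dp is not None else None,
                        alt_count=int(alt_count) if alt_count is not None else None,
                        genotype=genotype,
                    ))
    return calls


def write_bed(path: str | Path, track: Sequence[tuple[str, int, int, int]]) -> None:
    with open(path, "w") as fh:
        for scaffold, start, end, depth in track:
            fh.write(f"{scaffold}\t{start}\t{end}\t{depth}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, int]]:
    track = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            scaffold, start, end, depth = line.split("\t")
            track.append((scaffold, int(start), int(end), int(depth)))
    return track


def write_pool_tsv(path: str | Path, sites: Sequence[PoolSite]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(POOL_COLUMNS)
        for s in sites:
            ac = s.allele_counts
            w.writerow([
                s.scaffold, s.pos, s.depth,
                ac.get("A", 0), ac.get("C", 0), ac.get("G", 0), ac.get("T", 0),
                ac.get("INS", 0), ac.get("DEL", 0),
            ])


def read_pool_tsv(path: str | Path) -> list[PoolSite]:
    sites = []
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            counts = {
                "A": int(row["countA"]), "C": int(row["countC"]),
                "G": int(row["countG"]), "T": int(row["countT"]),
                "INS": int(row["ins_count"]), "DEL": int(row["del_count"]),
            }
            sites.append(PoolSite(
                scaffold=row["scaffold"], pos=int(row["pos_1based"]),
                depth=int(row["depth"]), allele_counts=counts,
            ))
    return sites


def write_pool_calls_tsv(path: str | Path, keys: Iterable[tuple]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["scaffold", "pos_1based", "ref", "alt"])
        for scaffold, pos, ref, alt in sorted(keys):
            w.writerow([scaffold, pos, ref, alt])


def read_pool_calls_tsv(path: str | Path) -> set[tuple[str, int, str, str]]:
    keys = set()
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            keys.add((row["scaffold"], int(row["pos_1based"]),
                      row["ref"], row["alt"]))
    return keys


def write_truth_tsv(path: str | Path, truth) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["line_id", "origin_generation", "scaffold", "pos",
                    "mtype", "ref", "alt", "carrier_haplotypes"])
        for m in truth:
            w.writerow([m.line_id, m.origin_generation, m.scaffold, m.pos,
                        m.mtype, m.ref, m.alt,
                        ",".join(str(h) for h in sorted(m.carrier_haplotypes))])


def read_truth_tsv(path: str | Path):
    from .simdata import TrueMutation

    truth = []
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            haps = frozenset(
                int(h) for h in row["carrier_haplotypes"].split(",") if h
            )
            truth.append(TrueMutation(
                line_id=row["line_id"],
                origin_generation=int(row["origin_generation"]),
                scaffold=row["scaffold"], pos=int(row["pos"]),
                mtype=row["mtype"], ref=row["ref"], alt=row["alt"],
                carrier_haplotypes=haps,
            ))
    return truth


def write_contaminants_tsv(path: str | Path,
                           contaminants: Mapping[tuple, str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["line_id", "scaffold", "pos", "ref", "alt", "kind"])
        for (line_id, scaffold, pos, ref, alt), kind in sorted(
            contaminants.items()
        ):
            w.writerow([line_id, scaffold, pos, ref, alt, kind])


def read_contaminants_tsv(path: str | Path) -> dict[tuple, str]:
    out = {}
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            out[(row["line_id"], row["scaffold"], int(row["pos"]),
                 row["ref"], row["alt"])] = row["kind"]
    return out


def write_mutations_tsv(path: str | Path, records) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["line_id", "scaffold", "pos", "ref", "alt", "mtype",
                    "ts_tv", "gc_at_direction", "run_context_length",
                    "multi_allelic_site", "zygosity", "review_flag"])
        for m in records:
            w.writerow([m.line_id, m.scaffold, m.pos, m.ref, m.alt, m.mtype,
                        m.ts_tv, m.gc_at_direction, m.run_context_length,
                        int(m.multi_allelic_site), m.zygosity,
                        int(m.review_flag)])


def read_mutations_tsv(path: str | Path):
    from .dnmcall import MutationRecord

    records = []
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            records.append(MutationRecord(
                line_id=row["line_id"], scaffold=row["scaffold"],
                pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                mtype=row["mtype"], ts_tv=row["ts_tv"],
                gc_at_direction=row["gc_at_direction"],
                run_context_length=int(row["run_context_length"]),
                multi_allelic_site=bool(int(row["multi_allelic_site"])),
                zygosity=row["zygosity"],
                review_flag=bool(int(row["review_flag"])),
            ))
    return records
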