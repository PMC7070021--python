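"""Readers and writers for the pipeline's plain-text formats.

Formats: FASTA (strict {A,C,G,T,N} alphabet, errors name the offending
line), depth histograms as two-column ``depth,count`` CSV (the ``histo``
output convention of common k-mer counters), GenAlEx-style codominant
genotype CSV, STRUCTURE two-row genotype text (integer alleles, -9
missing), and flow-cytometry replicate CSV.  All writers are loss-free
for their readers.
"""

from __future__ import annotations

import csv

from .containers import GenotypeMatrix, KmerHistogram
from .cytometry import CytometryRun

VALID = set("ACGTN")


# --- FASTA -----------------------------------------------------------------


def read_fasta(path):
    """Strict FASTA reader: list of (id, sequence); upcases lowercase."""
    records = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    if not chunks:
                        raise ValueError(f"empty record {header!r} before line {lineno}")
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ValueError(f"malformed header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"sequence before any header at line {lineno}")
                seq = line.upper()
                bad = set(seq) - VALID
                if bad:
                    raise ValueError(
                        f"invalid characters {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
    if header is not None:
        if not chunks:
            raise ValueError(f"empty record {header!r} at end of file")
        records.append((header, "".join(chunks)))
    return records


def write_fasta(sequences, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in sequences:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- k-mer histogram CSV ---------------------------------------------------


def read_histogram(path, k: int = 17) -> KmerHistogram:
    counts: dict[int, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or row[0].lower() in ("depth", "#depth"):
                continue
            counts[int(row[0])] = int(row[1])
    return KmerHistogram(k=k, counts=counts)


def write_histogram(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("depth,count\n")
        for depth in sorted(hist.counts):
            fh.write(f"{depth},{hist.counts[depth]}\n")


# --- genotype dialects -----------------------------------------------------

MISSING_SENTINELS = {"-9", "0", "", "NA"}


def read_genotypes(path, dialect: str = "genalex") -> GenotypeMatrix:
    """Read a codominant diploid genotype table.

    Dialects:

    * ``genalex`` — CSV with header ``id,group,<locus>,<locus>,...``
      (two columns per locus, paired alleles); missing as -9, 0 or blank.
    * ``structure`` — whitespace two-row format: each individual spans
      two consecutive rows ``id [group] a_1 ... a_L``, integer alleles,
      -9 missing.
    """
    if dialect == "genalex":
        return _read_genalex(path)
    if dialect == "structure":
        return _read_structure(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _normalize(a: str):
    a = a.strip()
    return None if a in MISSING_SENTINELS else a


def _read_genalex(path) -> GenotypeMatrix:
    with open(path) as fh:
        rows = [r for r in csv.reader(fh) if any(f.strip() for f in r)]
    header = rows[0]
    locus_cols = header[2:]
    if len(locus_cols) % 2:
        raise ValueError("GenAlEx header needs two columns per locus")
    loci = [locus_cols[i] for i in range(0, len(locus_cols), 2)]
    individuals, labels, calls = [], [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(f"ragged row {r}: {len(row)} fields, expected {len(header)}")
        individuals.append(row[0].strip())
        labels.append(row[1].strip())
        pair_row = []
        for i in range(2, len(row), 2):
            a, b = _normalize(row[i]), _normalize(row[i + 1])
            if (a is None) != (b is None):
                raise ValueError(f"half-missing call for {row[0]!r} (row {r})")
            pair_row.append((a, b))
        calls.append(pair_row)
    return GenotypeMatrix(individuals, loci, calls, labels=labels)


def _read_structure(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError("empty genotype file")
    header: list[str] | None = None
    first = lines[0]
    # optional locus-name header: a row with no numeric fields
    if all(not _looks_numeric(f) for f in first):
        header = first
        lines = lines[1:]
        if not lines:
            raise ValueError("no genotype rows after locus header")
    elif not _looks_numeric(first[-1]):
        raise ValueError("STRUCTURE rows must end in integer alleles")
    if len(lines) % 2:
        raise ValueError("two-row format needs an even number of data rows")
    width = len(lines[0])
    n_meta = None
    individuals, labels, calls = [], [], []
    for i in range(0, len(lines), 2):
        r1, r2 = lines[i], lines[i + 1]
        if len(r1) != width or len(r2) != width:
            raise ValueError(f"ragged rows for individual starting at data row {i + 1}")
        if r1[0] != r2[0]:
            raise ValueError(f"row pair mismatch: {r1[0]!r} vs {r2[0]!r}")
        if n_meta is None:
            n_meta = 1
            if len(r1) > 1 and not _looks_numeric(r1[1]):
                n_meta = 2
        individuals.append(r1[0])
        labels.append(r1[1] if n_meta == 2 else "")
        pair_row = []
        for a, b in zip(r1[n_meta:], r2[n_meta:]):
            a, b = _normalize(a), _normalize(b)
            if (a is None) != (b is None):
                raise ValueError(f"half-missing call for {r1[0]!r}")
            pair_row.append((a if a is None else int(a), b if b is None else int(b)))
        calls.append(pair_row)
    n_loci = len(calls[0])
    loci = header if header else [f"L{j + 1}" for j in range(n_loci)]
    if len(loci) != n_loci:
        raise ValueError("locus header length does not match genotype columns")
    labels_out = labels if any(labels) else None
    return GenotypeMatrix(individuals, loci, calls, labels=labels_out)


def _looks_numeric(field: str) -> bool:
    try:
        int(field)
        return True
    except ValueError:
        return False


def write_genotypes(G: GenotypeMatrix, path, dialect: str = "genalex") -> None:
    if dialect == "genalex":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["id", "group"]
            for locus in G.loci:
                header += [str(locus), f"{locus}_b"]
            w.writerow(header)
            for i, ind in enumerate(G.individuals):
                row = [ind, G.labels[i] if G.labels else ""]
                for l in range(G.n_loci):
                    a, b = G.calls[i, l]
                    row += ["-9", "-9"] if a is None else [str(a), str(b)]
                w.writerow(row)
    elif dialect == "structure":
        with open(path, "w") as fh:
            for i, ind in enumerate(G.individuals):
                for c in (0, 1):
                    fields = [str(ind)]
                    if G.labels:
                        fields.append(str(G.labels[i]))
                    for l in range(G.n_loci):
                        a = G.calls[i, l, c]
                        fields.append("-9" if a is None else str(a))
                    fh.write(" ".join(fields) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# --- cytometry CSV ---------------------------------------------------------


def read_cytometry(path, standards: dict):
    """Replicate CSV -> list of CytometryRun, one per standard.

    Columns: ``replicate,standard_name,sample_peak,standard_peak,peak_cv``.
    ``standards`` maps standard name -> known 2C value (pg).
    """
    runs: dict[str, CytometryRun] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            name = row["standard_name"].strip()
            if name not in standards:
                raise ValueError(f"unknown standard {name!r}")
            run = runs.setdefault(
                name, CytometryRun(standard_name=name, standard_2c_pg=standards[name])
            )
            run.replicates.append(
                (float(row["sample_peak"]), float(row["standard_peak"]), float(row["peak_cv"]))
            )
    return list(runs.values())


def write_cytometry(runs, path) -> None:
    with open(path, "w") as fh:
        fh.write("replicate,standard_name,sample_peak,standard_peak,peak_cv\n")
        for run in runs if isinstance(runs, list) else [runs]:
            for i, (s, t, cv) in enumerate(run.replicates, start=1):
                fh.write(f"{i},{run.standard_name},{s:.6g},{t:.6g},{cv:.6g}\n")
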