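"""GO term annotation of gene modules.

Two online providers are supported — the g:Profiler g:GOSt and ToppGene
ToppFun REST endpoints — plus a deterministic offline engine based on the
one-sided hypergeometric tail with Bonferroni correction, for tests and
air-gapped use. For queries drawn from a limited SRT gene panel the full
measured panel is sent as the background universe (g:Profiler only; the
ToppGene API supports neither custom backgrounds nor organisms, so it is
reserved for transcriptome-wide queries where no background is used).
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

GPROFILER_URL = "https://biit.cs.ut.ee/gprofiler/api/gost/profile/"
TOPPGENE_URL = "https://toppgene.cchmc.org/API/enrich"

PROVIDERS = ("gprofiler", "toppgene", "offline")


class ConfigError(ValueError):
    """Invalid query configuration, detected before any network call."""


class TransportError(RuntimeError):
    """HTTP or parse failure; retriable, distinct from an empty result set."""


@dataclass
class EnrichmentQuery:
    """A gene-set overrepresentation query.

    ``background_genes``, when present, must be a superset of the query
    (the SRT panel universe). ToppGene forbids both a background and a
    custom organism.
    """

    query_genes: list[str]
    background_genes: list[str] | None = None
    organism: str = "mmusculus"
    provider: str = "gprofiler"
    correction: str = "bonferroni"
    term_table: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if not self.query_genes:
            raise ConfigError("query requires at least one gene")
        if self.provider not in PROVIDERS:
            raise ConfigError(f"provider must be one of {PROVIDERS}")
        if self.background_genes is not None:
            missing = set(self.query_genes) - set(self.background_genes)
            if missing:
                raise ConfigError(
                    f"background must be a superset of the query; missing "
                    f"{sorted(missing)}"
                )
        if self.provider == "toppgene" and self.background_genes is not None:
            raise ConfigError(
                "the ToppGene API does not support a custom background; "
                "use gprofiler for SRT-panel queries"
            )


@dataclass
class EnrichmentResult:
    """Enriched terms sorted by ascending adjusted p-value."""

    rows: pd.DataFrame  # columns: term_id, term_name, p_adjusted, overlap_genes
    provider: str
    query_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = ["term_id", "term_name", "p_adjusted", "overlap_genes"]
        for col in required:
            if col not in self.rows.columns:
                raise ValueError(f"result rows missing column {col!r}")
        self.rows = self.rows.sort_values(
            ["p_adjusted", "term_id"], kind="stable"
        ).reset_index(drop=True)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.rows.copy()
        df["overlap_genes"] = df["overlap_genes"].map(
            lambda g: ";".join(g) if not isinstance(g, str) else g
        )
        return df


def hypergeometric_tail(
    overlap: int, universe_size: int, term_size: int, query_size: int
) -> float:
    """P(X >= overlap) for X hypergeometric(universe, term, query draws)."""
    return float(hypergeom.sf(overlap - 1, universe_size, term_size, query_size))


def enrich_offline(
    query_genes: list[str],
    background_genes: list[str],
    term_table: dict[str, list[str]],
    correction: str = "bonferroni",
    term_names: dict[str, str] | None = None,
) -> EnrichmentResult:
    """Hypergeometric overrepresentation test against a local term table.

    For each term: population = background, successes = term genes present
    in the background, draws = query size, and p is the one-sided upper tail
    at the observed overlap. Bonferroni multiplies by the number of terms
    tested (terms with >= 1 gene in the background), capped at 1. Terms
    with no overlapping query gene are omitted from the result rows but
    still count toward the correction.
    """
    if not background_genes:
        raise ConfigError("offline enrichment requires a background universe")
    if correction != "bonferroni":
        raise ConfigError(f"unsupported correction {correction!r}")
    bg = set(background_genes)
    missing = set(query_genes) - bg
    if missing:
        raise ConfigError(
            f"background must be a superset of the query; missing {sorted(missing)}"
        )
    universe = len(bg)
    n_query = len(set(query_genes))
    tested = {
        tid: set(genes) & bg
        for tid, genes in term_table.items()
        if set(genes) & bg
    }
    m = len(tested)
    records = []
    for tid, term_genes in tested.items():
        overlap = [g for g in query_genes if g in term_genes]  # query order
        if not overlap:
            continue
        p = hypergeometric_tail(len(overlap), universe, len(term_genes), n_query)
        records.append(
            {
                "term_id": tid,
                "term_name": (term_names or {}).get(tid, tid),
                "p_adjusted": min(1.0, p * m),
                "overlap_genes": overlap,
            }
        )
    rows = pd.DataFrame(
        records, columns=["term_id", "term_name", "p_adjusted", "overlap_genes"]
    )
    return EnrichmentResult(rows=rows, provider="offline", query_genes=list(query_genes))


def enrich(
    query: EnrichmentQuery,
    *,
    timeout: float = 30.0,
    retries: int = 3,
    _transport=None,
) -> EnrichmentResult:
    """Run the query against its provider.

    ``_transport`` injects a callable ``(url, payload) -> parsed-json`` for
    record/replay testing; by default a urllib POST with exponential-backoff
    retries is used.
    """
    if query.provider == "offline":
        if query.term_table is None:
            raise ConfigError("offline provider requires a term_table")
        return enrich_offline(
            query.query_genes,
            query.background_genes or sorted(
                set(query.query_genes)
                | {g for gs in query.term_table.values() for g in gs}
            ),
            query.term_table,
            query.correction,
        )
    transport = _transport or _http_post_json
    if query.provider == "gprofiler":
        payload = {
            "organism": query.organism,
            "query": query.query_genes,
            "sources": ["GO:BP", "GO:MF", "GO:CC"],
            "user_threshold": 0.05,
            "significance_threshold_method": query.correction,
            "no_evidences": False,
        }
        if query.background_genes is not None:
            payload["background"] = query.background_genes
            payload["domain_scope"] = "custom"
        data = _with_retries(transport, GPROFILER_URL, payload, timeout, retries)
        records = []
        for r in data.get("result", []):
            ev = r.get("intersections") or []
            overlap = [
                g for g, hits in zip(query.query_genes, ev) if hits
            ] or list(r.get("intersection_genes", []))
            records.append(
                {
                    "term_id": r["native"],
                    "term_name": r.get("name", r["native"]),
                    "p_adjusted": float(r["p_value"]),
                    "overlap_genes": overlap,
                }
            )
    else:  # toppgene
        payload = {"Symbols": query.query_genes, "Categories": [
            {"Type": "GeneOntologyBiologicalProcess", "PValue": 0.05,
             "Correction": "Bonferroni"},
            {"Type": "GeneOntologyMolecularFunction", "PValue": 0.05,
             "Correction": "Bonferroni"},
            {"Type": "GeneOntologyCellularComponent", "PValue": 0.05,
             "Correction": "Bonferroni"},
        ]}
        data = _with_retries(transport, TOPPGENE_URL, payload, timeout, retries)
        records = []
        for r in data.get("Annotations", []):
            overlap = [g["Symbol"] for g in r.get("Genes", [])]
            overlap = [g for g in query.query_genes if g in set(overlap)]
            records.append(
                {
                    "term_id": r.get("ID", r.get("Name", "")),
                    "term_name": r.get("Name", ""),
                    "p_adjusted": float(
                        r.get("QValueBonferroni", r.get("PValue", 1.0))
                    ),
                    "overlap_genes": overlap,
                }
            )
    rows = pd.DataFrame(
        records, columns=["term_id", "term_name", "p_adjusted", "overlap_genes"]
    )
    return EnrichmentResult(
        rows=rows, provider=query.provider, query_genes=list(query.query_genes)
    )


def genes_for_term(result: EnrichmentResult, term_id: str) -> list[str]:
    """Overlap gene list of one term, preserving query order."""
    hit = result.rows[result.rows["term_id"] == term_id]
    if hit.empty:
        raise KeyError(f"term {term_id!r} not in results")
    genes = hit.iloc[0]["overlap_genes"]
    if isinstance(genes, str):
        genes = genes.split(";") if genes else []
    return list(genes)


def load_term_table(path: str | Path) -> dict[str, list[str]]:
    """Load a term -> gene-set map from two-column TSV or GMT.

    TSV: one ``term_id<TAB>gene_symbol`` pair per line.
    GMT: ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.
    """
    path = Path(path)
    table: dict[str, list[str]] = {}
    fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if fmt == "gmt":
            tid, genes = parts[0], parts[2:]
            table.setdefault(tid, []).extend(g for g in genes if g)
        else:
            if len(parts) != 2:
                raise ValueError(
                    f"expected two tab-separated columns, got {len(parts)}: {line!r}"
                )
            table.setdefault(parts[0], []).append(parts[1])
    return table


def _http_post_json(url: str, payload: dict, timeout: float = 30.0) -> dict:
    req = urllib.request.Request(
        url,
        data=json.dumps(payload).encode(),
        headers={"Content-Type": "application/json", "Accept": "application/json"},
    )
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            return json.loads(resp.read().decode())
    except (urllib.error.URLError, json.JSONDecodeError, TimeoutError) as e:
        raise TransportError(f"request to {url} failed: {e}") from e


def _with_retries(transport, url, payload, timeout, retries) -> dict:
    delay = 1.0
    last: Exception | None = None
    for _ in range(max(1, retries)):
        try:
            return transport(url, payload, timeout)
        except TransportError as e:
            last = e
            time.sleep(delay)
            delay *= 2
    raise last  # type: ignore[misc]
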