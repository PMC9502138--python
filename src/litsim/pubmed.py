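"""PubMed text collection through the NCBI E-utilities.

Two entry points mirror the text-collection tools of the workflow:
``populate_by_queries`` searches PubMed with each entity's free-text query
(ESearch) and optionally fetches the matching abstracts (EFetch), while
``populate_abstracts_by_pmids`` fetches abstracts for pre-curated PMIDs.
Both return a new table; pre-existing custom texts are preserved, because
custom text can be analyzed instead of or in addition to collected text.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET

from .data_model import AbstractRecord, EntityTable
from .errors import PayloadParseError, ValidationError
from .transport import Transport

__all__ = [
    "search_pmids",
    "fetch_abstracts",
    "populate_by_queries",
    "populate_abstracts_by_pmids",
]

logger = logging.getLogger(__name__)

#: E-utilities caps retmax at 10000 ids per ESearch page.
SEARCH_PAGE_SIZE = 10_000
#: EFetch batches at most this many PMIDs per request.
FETCH_BATCH_SIZE = 200


def _collapse(text: str) -> str:
    return " ".join(text.split())


def search_pmids(
    query: str,
    max_n: int,
    transport: Transport,
    page_size: int = SEARCH_PAGE_SIZE,
) -> list[str]:
    """Search PubMed and return up to ``max_n`` PMIDs in relevance/return order.

    Paging is handled internally; the result is deduplicated preserving
    order.  ``max_n == 0`` short-circuits without any transport call.
    """
    if max_n < 0:
        raise ValidationError(f"max_n must be non-negative, got {max_n}")
    if not query:
        raise ValidationError("query must be non-empty")
    if max_n == 0:
        return []
    pmids: list[str] = []
    seen: set[str] = set()
    retstart = 0
    while len(pmids) < max_n:
        payload = transport.request(
            "esearch",
            {
                "db": "pubmed",
                "term": query,
                "retmax": str(min(page_size, max_n - len(pmids))),
                "retstart": str(retstart),
                "retmode": "xml",
            },
        )
        try:
            root = ET.fromstring(payload)
            count = int(root.findtext("Count", "0"))
            page = [el.text.strip() for el in root.iter("Id") if el.text]
        except (ET.ParseError, ValueError) as exc:
            raise PayloadParseError(f"malformed ESearch payload for {query!r}: {exc}") from exc
        for pmid in page:
            if pmid not in seen:
                seen.add(pmid)
                pmids.append(pmid)
        retstart += len(page)
        if not page or retstart >= count:
            break
    return pmids[:max_n]


def _parse_efetch(payload: str, include_title: bool) -> dict[str, str]:
    try:
        root = ET.fromstring(payload)
    except ET.ParseError as exc:
        raise PayloadParseError(f"malformed EFetch payload: {exc}") from exc
    out: dict[str, str] = {}
    for article in root.iter("PubmedArticle"):
        pmid = article.findtext("MedlineCitation/PMID")
        abstract = article.find("MedlineCitation/Article/Abstract")
        if pmid is None or abstract is None:
            continue
        paragraphs = [
            _collapse("".join(el.itertext()))
            for el in abstract.findall("AbstractText")
        ]
        paragraphs = [p for p in paragraphs if p]
        if not paragraphs:
            continue
        parts = []
        if include_title:
            title = article.find("MedlineCitation/Article/ArticleTitle")
            if title is not None:
                t = _collapse("".join(title.itertext()))
                if t:
                    parts.append(t)
        parts.extend(paragraphs)
        out[pmid.strip()] = " ".join(parts)
    return out


def fetch_abstracts(
    pmids: list[str],
    transport: Transport,
    include_title: bool = True,
    batch_size: int = FETCH_BATCH_SIZE,
) -> list[AbstractRecord]:
    """Fetch abstracts for PMIDs, one record per PMID that has an abstract.

    Output order follows input order; PMIDs without an abstract are dropped
    with a logged skip (common for very old records).  Requests are batched.
    """
    for pmid in pmids:
        if not pmid.isdigit():
            raise ValidationError(f"PMID {pmid!r} is not all-digit")
    if not pmids:
        return []
    found: dict[str, str] = {}
    for start in range(0, len(pmids), batch_size):
        batch = pmids[start : start + batch_size]
        payload = transport.request(
            "efetch",
            {"db": "pubmed", "id": ",".join(batch), "retmode": "xml"},
        )
        found.update(_parse_efetch(payload, include_title))
    records = []
    for pmid in pmids:
        if pmid in found:
            records.append(AbstractRecord(pmid=pmid, text=found[pmid]))
        else:
            logger.warning("PMID %s has no abstract; skipped", pmid)
    return records


def populate_by_queries(
    table: EntityTable,
    mode: str,
    max_n: int,
    transport: Transport,
    include_title: bool = True,
) -> EntityTable:
    """Search PubMed with each entity's query and fill PMIDs and/or abstracts.

    ``mode='pmids'`` fills each record's PMID list; ``mode='abstracts'``
    additionally fetches the abstracts into the record's texts (the searched
    PMIDs are recorded too, so a downstream concept-annotation stage does not
    need to re-search).  Entities whose query returns nothing are kept with
    empty lists and logged.
    """
    if mode not in ("pmids", "abstracts"):
        raise ValidationError(f"mode must be 'pmids' or 'abstracts', got {mode!r}")
    missing = [r.entity_id for r in table.records if not r.query]
    if missing:
        raise ValidationError(f"entities without a query: {', '.join(missing)}")
    new_records = []
    for rec in table.records:
        pmids = search_pmids(rec.query, max_n, transport)
        if not pmids:
            logger.warning("query for entity %s returned no hits", rec.entity_id)
            new_records.append(rec.replace())
            continue
        if mode == "pmids":
            new_records.append(rec.replace(pmids=pmids))
        else:
            abstracts = fetch_abstracts(pmids, transport, include_title=include_title)
            new_records.append(
                rec.replace(pmids=pmids, texts=rec.texts + [a.text for a in abstracts])
            )
    return EntityTable(new_records, grouping_columns=list(table.grouping_columns))


def populate_abstracts_by_pmids(
    table: EntityTable,
    transport: Transport,
    include_title: bool = True,
) -> EntityTable:
    """Fetch abstracts for each record's curated PMIDs, appending to any
    pre-existing custom texts."""
    if not any(r.pmids for r in table.records):
        raise ValidationError("no record has PMIDs to fetch")
    new_records = []
    for rec in table.records:
        if not rec.pmids:
            new_records.append(rec.replace())
            continue
        abstracts = fetch_abstracts(rec.pmids, transport, include_title=include_title)
        new_records.append(rec.replace(texts=rec.texts + [a.text for a in abstracts]))
    return EntityTable(new_records, grouping_columns=list(table.grouping_columns))
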