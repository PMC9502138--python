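"""PubTator concept annotations as scientific terms.

PubTator provides pre-computed annotations of biomedical concepts (genes,
diseases, chemicals, mutations, species, cell lines) in PubMed abstracts.
``fetch_annotations`` pulls BioC-JSON payloads per PMID batch and filters to
the requested categories; ``normalize_concept`` turns an annotation into a
matrix term, by default at identifier level so synonymous mentions merge.
"""

from __future__ import annotations

import json
import logging

from .data_model import CONCEPT_CATEGORIES, ConceptAnnotation
from .errors import PayloadParseError, ValidationError
from .transport import Transport

__all__ = ["fetch_annotations", "normalize_concept", "ANNOTATION_BATCH_SIZE"]

logger = logging.getLogger(__name__)

ANNOTATION_BATCH_SIZE = 100

# PubTator annotation types -> our category names; variant subtypes collapse
# onto "mutation".
_TYPE_TO_CATEGORY = {
    "gene": "gene",
    "disease": "disease",
    "chemical": "chemical",
    "mutation": "mutation",
    "variant": "mutation",
    "snp": "mutation",
    "dnamutation": "mutation",
    "proteinmutation": "mutation",
    "species": "species",
    "cellline": "cellline",
}


def _iter_documents(payload: str):
    """BioC-JSON comes either as one JSON object per line or a single list."""
    payload = payload.strip()
    if not payload:
        return
    if payload.startswith("["):
        yield from json.loads(payload)
        return
    for line in payload.splitlines():
        line = line.strip()
        if line:
            yield json.loads(line)


def _parse_documents(payload: str, categories: set[str]) -> list[ConceptAnnotation]:
    annotations = []
    try:
        for doc in _iter_documents(payload):
            pmid = str(doc.get("pmid") or doc.get("id") or "").strip()
            for passage in doc.get("passages", []):
                for ann in passage.get("annotations", []):
                    infons = ann.get("infons", {})
                    category = _TYPE_TO_CATEGORY.get(str(infons.get("type", "")).lower())
                    if category is None or category not in categories:
                        continue
                    identifier = infons.get("identifier") or infons.get("MESH")
                    if identifier in ("-", "None", ""):
                        identifier = None
                    mention = str(ann.get("text", "")).strip()
                    if not mention:
                        continue
                    annotations.append(
                        ConceptAnnotation(
                            pmid=pmid,
                            category=category,
                            concept_id=str(identifier) if identifier else None,
                            mention=mention,
                        )
                    )
    except (json.JSONDecodeError, AttributeError, TypeError) as exc:
        raise PayloadParseError(f"malformed PubTator payload: {exc}") from exc
    return annotations


def fetch_annotations(
    pmids: list[str],
    categories: set[str],
    transport: Transport,
    batch_size: int = ANNOTATION_BATCH_SIZE,
) -> list[ConceptAnnotation]:
    """Fetch concept annotations for PMIDs, restricted to ``categories``.

    Requests are batched; PMIDs unknown to the service simply yield no
    annotations (logged).  Category filtering is exact set membership.
    """
    categories = set(categories)
    if not categories:
        raise ValidationError("categories must be a non-empty set")
    invalid = categories - set(CONCEPT_CATEGORIES)
    if invalid:
        raise ValidationError(
            f"unknown categories {sorted(invalid)}; valid: {', '.join(CONCEPT_CATEGORIES)}"
        )
    annotations: list[ConceptAnnotation] = []
    for start in range(0, len(pmids), batch_size):
        batch = pmids[start : start + batch_size]
        payload = transport.request("pubtator", {"pmids": ",".join(batch)})
        wanted = set(batch)
        annotations.extend(
            a for a in _parse_documents(payload, categories) if a.pmid in wanted
        )
    covered = {a.pmid for a in annotations}
    for pmid in pmids:
        if pmid not in covered:
            logger.info("PMID %s: no annotations in requested categories", pmid)
    return annotations


def normalize_concept(annotation: ConceptAnnotation, by_id: bool = True) -> str:
    """Turn an annotation into a matrix term.

    With ``by_id`` (the default) a normalized concept becomes
    ``"<category>:<identifier>"`` so synonymous mentions of one concept merge
    into one term; annotations without an identifier, and all annotations
    when ``by_id`` is off, fall back to the lowercased, whitespace-collapsed
    mention text.
    """
    if by_id and annotation.concept_id:
        return f"{annotation.category}:{annotation.concept_id}"
    return " ".join(annotation.mention.lower().split())
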