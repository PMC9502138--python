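"""Shared fixtures: toy entity tables and canned service payloads."""

from __future__ import annotations

import json

import pytest

from litsim.data_model import EntityRecord, EntityTable
from litsim.transport import FixtureTransport


def esearch_xml(ids, count=None):
    count = len(ids) if count is None else count
    id_items = "".join(f"<Id>{i}</Id>" for i in ids)
    return (
        f"<eSearchResult><Count>{count}</Count><RetMax>{len(ids)}</RetMax>"
        f"<RetStart>0</RetStart><IdList>{id_items}</IdList></eSearchResult>"
    )


def efetch_xml(abstracts, titles=None):
    """abstracts: dict pmid -> abstract text (None = record without abstract)."""
    titles = titles or {}
    articles = []
    for pmid, text in abstracts.items():
        title = titles.get(pmid, "")
        title_xml = f"<ArticleTitle>{title}</ArticleTitle>" if title else ""
        abstract_xml = (
            f"<Abstract><AbstractText>{text}</AbstractText></Abstract>"
            if text is not None else ""
        )
        articles.append(
            "<PubmedArticle><MedlineCitation>"
            f"<PMID>{pmid}</PMID><Article>{title_xml}{abstract_xml}</Article>"
            "</MedlineCitation></PubmedArticle>"
        )
    return f"<PubmedArticleSet>{''.join(articles)}</PubmedArticleSet>"


def pubtator_json(docs):
    """docs: dict pmid -> list of (type, identifier, mention)."""
    payload = []
    for pmid, anns in docs.items():
        payload.append({
            "id": pmid,
            "passages": [{
                "annotations": [
                    {"infons": {"type": t, "identifier": i}, "text": m}
                    for t, i, m in anns
                ]
            }],
        })
    return json.dumps(payload)


@pytest.fixture
def toy_table():
    return EntityTable(
        records=[
            EntityRecord("geneA", grouping={"CATEGORY": "epilepsy"},
                         query="geneA AND epilepsy"),
            EntityRecord("geneB", grouping={"CATEGORY": "cancer"},
                         query="geneB AND tumor"),
        ],
        grouping_columns=["CATEGORY"],
    )


@pytest.fixture
def pubmed_transport():
    """Fixture transport: geneA query hits 5 PMIDs, geneB hits 2; abstracts
    exist for all but PMID 999."""
    t = FixtureTransport()
    t.add("esearch", {"term": "geneA AND epilepsy"},
          esearch_xml(["11", "12", "13", "14", "15"]))
    t.add("esearch", {"term": "geneB AND tumor"}, esearch_xml(["21", "999"]))
    t.add("esearch", {"term": "nohits"}, esearch_xml([]))
    t.add("efetch", {}, efetch_xml(
        {"11": "Ion channel dysfunction in epilepsy.",
         "12": "Sodium channel mutations cause seizures.",
         "13": "Channelopathies and seizure disorders.",
         "14": "Epileptic encephalopathy genetics.",
         "15": "Seizure phenotypes in channelopathy.",
         "21": "Tumor suppressor pathways in cancer.",
         "123": "Some abstract.",
         "999": None},
    ))
    return t


@pytest.fixture
def pubtator_transport():
    t = FixtureTransport()
    t.add("pubtator", {}, pubtator_json({
        "11": [("Gene", "6323", "SCN1A"), ("Disease", "MESH:D004827", "epilepsy")],
        "12": [("Gene", "6323", "Scn1a"), ("Disease", None, "Dravet  Syndrome")],
        "21": [("Chemical", "MESH:D013256", "steroids")],
    }))
    return t
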