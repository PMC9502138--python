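"""Pluggable request transports for the PubMed and PubTator clients.

A transport maps ``(endpoint, parameters)`` to a raw text payload.  The live
transport speaks HTTP with NCBI rate limiting and retry; the fixture
transport replays packaged payloads deterministically so the whole retrieval
layer runs offline in tests and demos.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from pathlib import Path
from typing import Protocol

from .errors import RetrievalError

__all__ = ["Transport", "LiveTransport", "FixtureTransport", "ENDPOINT_URLS"]

ENDPOINT_URLS = {
    "esearch": "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi",
    "efetch": "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi",
    "pubtator": (
        "https://www.ncbi.nlm.nih.gov/research/pubtator-api/"
        "publications/export/biocjson"
    ),
}


class Transport(Protocol):
    """Request executor contract: symbolic endpoint + params -> payload text."""

    def request(self, endpoint: str, params: dict[str, str]) -> str:  # pragma: no cover
        ...


class LiveTransport:
    """HTTP transport for the NCBI services.

    Enforces the E-utilities etiquette: at most 3 requests/second without an
    API key, 10 with one; transient failures are retried up to ``max_retries``
    times with exponential backoff.
    """

    def __init__(self, api_key: str | None = None, max_retries: int = 3,
                 timeout: float = 30.0) -> None:
        self.api_key = api_key
        self.max_retries = max_retries
        self.timeout = timeout
        self._min_interval = 0.1 if api_key else 1.0 / 3.0
        self._last_request = 0.0

    def request(self, endpoint: str, params: dict[str, str]) -> str:
        if endpoint not in ENDPOINT_URLS:
            raise RetrievalError(f"unknown endpoint {endpoint!r}")
        params = dict(params)
        if self.api_key and endpoint in ("esearch", "efetch"):
            params["api_key"] = self.api_key
        url = ENDPOINT_URLS[endpoint] + "?" + urllib.parse.urlencode(params)
        delay = 1.0
        for attempt in range(self.max_retries + 1):
            wait = self._min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read().decode("utf-8")
            except (urllib.error.URLError, TimeoutError) as exc:
                if attempt == self.max_retries:
                    raise RetrievalError(
                        f"{endpoint} request failed after "
                        f"{self.max_retries + 1} attempts: {exc}"
                    ) from exc
                time.sleep(delay)
                delay *= 2


class FixtureTransport:
    """Deterministic replay transport.

    Entries are ``{"endpoint": str, "params": {...}, "body": str}``; a request
    matches the first entry whose endpoint equals the request's and whose
    recorded params are a subset of the request params (values compared as
    strings).  Entries can be passed directly or loaded from ``*.json`` files
    in a directory (each file holding one entry or a list of entries).
    """

    def __init__(self, entries: list[dict] | None = None) -> None:
        self.entries = list(entries or [])
        self.calls: list[tuple[str, dict[str, str]]] = []

    @classmethod
    def from_dir(cls, directory) -> "FixtureTransport":
        entries = []
        for path in sorted(Path(directory).glob("*.json")):
            loaded = json.loads(path.read_text(encoding="utf-8"))
            entries.extend(loaded if isinstance(loaded, list) else [loaded])
        return cls(entries)

    def add(self, endpoint: str, params: dict, body: str) -> None:
        self.entries.append({"endpoint": endpoint, "params": params, "body": body})

    def request(self, endpoint: str, params: dict[str, str]) -> str:
        self.calls.append((endpoint, dict(params)))
        req = {k: str(v) for k, v in params.items()}
        for entry in self.entries:
            if entry["endpoint"] != endpoint:
                continue
            want = {k: str(v) for k, v in entry.get("params", {}).items()}
            if all(req.get(k) == v for k, v in want.items()):
                return entry["body"]
        raise RetrievalError(
            f"no fixture entry matches {endpoint} request with params {params}"
        )
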