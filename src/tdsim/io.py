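"""Readers and writers for TDS event logs and generator configs.

Two interchange formats are supported:

* **Long-format CSV** — one row per button press with columns
  ``trial_id,panel_id,replicate,attribute,onset_seconds``. Each trial's rows
  are delimited by sentinel attributes ``START`` and ``STOP`` carrying the
  start/stop timestamps; all timestamps are seconds, "." decimal, UTF-8.
* **JSON document** — embeds the lexicon and full trial fidelity; event times
  are either pre-normalized (``"normalized": true``) or in seconds with
  explicit ``start``/``stop``.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import yaml

from .errors import LexiconError, ParseError, TDSError
from .lexicon import AttributeLexicon
from .simulate import SemiMarkovSpec
from .trial import TDSTrial, TrialSet, build_trial

__all__ = [
    "read_trials",
    "write_trials",
    "read_lexicon",
    "load_spec",
    "save_spec",
]

_START, _STOP = "START", "STOP"
_CSV_COLUMNS = ["trial_id", "panel_id", "replicate", "attribute", "onset_seconds"]


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise TDSError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".csv", ".json"):
        return suffix[1:]
    raise TDSError(f"cannot infer format from {path!r}; pass format=")


def read_lexicon(path) -> AttributeLexicon:
    """Read an attribute lexicon: one label per line, blanks ignored."""
    with open(path, encoding="utf-8") as fh:
        names = [line.strip() for line in fh if line.strip()]
    return AttributeLexicon(names)


def read_trials(
    path, format: str | None = None, lexicon: AttributeLexicon | None = None
) -> TrialSet:
    """Read a TrialSet from a CSV event log or a JSON trial document.

    For CSV, the lexicon may be given explicitly; otherwise it is inferred
    from the attribute labels in order of first appearance (with a warning,
    since inferred ordering may differ between files). JSON documents embed
    their lexicon.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, lexicon)
    return _read_json(path, lexicon)


def _read_csv(path, lexicon: AttributeLexicon | None) -> TrialSet:
    groups: dict[str, list[tuple[int, dict]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c.strip() for c in reader.fieldnames
        ] != _CSV_COLUMNS:
            raise ParseError(
                f"{path}: expected header {','.join(_CSV_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            tid = (row["trial_id"] or "").strip()
            if not tid:
                raise ParseError(f"{path}:{lineno}: empty trial_id")
            groups.setdefault(tid, []).append((lineno, row))

    if lexicon is None:
        seen: list[str] = []
        for rows in groups.values():
            for _, row in rows:
                a = row["attribute"].strip()
                if a not in (_START, _STOP) and a not in seen:
                    seen.append(a)
        if not seen:
            raise ParseError(f"{path}: no attribute rows found")
        lexicon = AttributeLexicon(seen)
        warnings.warn(
            f"{path}: lexicon inferred from file in order of first "
            f"appearance: {seen}",
            stacklevel=3,
        )

    trials = []
    for tid, rows in groups.items():
        first_line, first = rows[0]
        last_line, last = rows[-1]
        if first["attribute"].strip() != _START:
            raise ParseError(
                f"{path}:{first_line}: trial {tid!r} must begin with a "
                f"{_START} row"
            )
        if last["attribute"].strip() != _STOP:
            raise ParseError(
                f"{path}:{last_line}: trial {tid!r} must end with a {_STOP} row"
            )
        try:
            start = float(first["onset_seconds"])
            stop = float(last["onset_seconds"])
            events = [
                (row["attribute"].strip(), float(row["onset_seconds"]))
                for _, row in rows[1:-1]
            ]
            replicate = int(first["replicate"] or 1)
        except ValueError as exc:
            raise ParseError(f"{path}: trial {tid!r}: bad numeric field: {exc}") from exc
        try:
            trials.append(
                build_trial(
                    events,
                    start=start,
                    stop=stop,
                    lexicon=lexicon,
                    trial_id=tid,
                    panel_id=(first["panel_id"] or "").strip(),
                    replicate=replicate,
                )
            )
        except LexiconError:
            raise
        except TDSError as exc:
            raise ParseError(
                f"{path}: trial {tid!r} (lines {first_line}-{last_line}): {exc}"
            ) from exc
    return TrialSet(lexicon, tuple(trials))


def _read_json(path, lexicon: AttributeLexicon | None) -> TrialSet:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    names = doc.get("lexicon") or doc.get("attributes")
    if names is not None:
        lexicon = AttributeLexicon(names)
    if lexicon is None:
        raise ParseError(f"{path}: document has no lexicon and none was given")
    trials = []
    for pos, td in enumerate(doc.get("trials", [])):
        tid = td.get("trial_id")
        if not tid:
            raise ParseError(f"{path}: trial #{pos} has no trial_id")
        raw = [(ev[0], float(ev[1])) for ev in td.get("events", [])]
        try:
            if td.get("normalized", False):
                events = tuple(
                    (
                        lexicon.index(a) if isinstance(a, str) else int(a),
                        onset,
                    )
                    for a, onset in raw
                )
                trials.append(
                    TDSTrial(
                        trial_id=tid,
                        events=events,
                        panel_id=td.get("panel_id", ""),
                        replicate=int(td.get("replicate", 1)),
                        duration_seconds=td.get("duration_seconds"),
                    )
                )
            else:
                if "start" not in td or "stop" not in td:
                    raise ParseError(
                        f"{path}: trial {tid!r}: seconds-based events need "
                        "start and stop"
                    )
                trials.append(
                    build_trial(
                        raw,
                        start=float(td["start"]),
                        stop=float(td["stop"]),
                        lexicon=lexicon,
                        trial_id=tid,
                        panel_id=td.get("panel_id", ""),
                        replicate=int(td.get("replicate", 1)),
                    )
                )
        except (LexiconError, ParseError):
            raise
        except TDSError as exc:
            raise ParseError(f"{path}: trial {tid!r}: {exc}") from exc
    return TrialSet(lexicon, tuple(trials))


def write_trials(trials: TrialSet, path, format: str | None = None) -> None:
    """Write a TrialSet; inverse of :func:`read_trials` (round-trip safe)."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(trials, path)
    else:
        _write_json(trials, path)


def _write_csv(trials: TrialSet, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for t in trials:
            dur = t.duration_seconds if t.duration_seconds is not None else 1.0
            meta = [t.trial_id, t.panel_id, t.replicate]
            writer.writerow(meta + [_START, repr(0.0)])
            for attr, onset in t.events:
                writer.writerow(
                    meta + [trials.lexicon.label(attr), repr(onset * dur)]
                )
            writer.writerow(meta + [_STOP, repr(dur)])


def _write_json(trials: TrialSet, path) -> None:
    doc = {
        "lexicon": list(trials.lexicon.names),
        "trials": [
            {
                "trial_id": t.trial_id,
                "panel_id": t.panel_id,
                "replicate": t.replicate,
                "duration_seconds": t.duration_seconds,
                "normalized": True,
                "events": [
                    [trials.lexicon.label(a), onset] for a, onset in t.events
                ],
            }
            for t in trials
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def load_spec(path) -> SemiMarkovSpec:
    """Load a semi-Markov generator spec from YAML (or JSON; YAML is a superset)."""
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return SemiMarkovSpec.from_dict(d)


def save_spec(spec: SemiMarkovSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
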