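"""Connected-speech fluency measures from picture-description transcripts.

Transcripts of the one-picture description task are coded in a minimal
CHAT-like plain-text dialect (one speaker line per input line) and reduced to
six measures: token count (T), type count, type-token ratio (TTR), morpheme
count, mean length of utterance in morphemes (MLU), and words per minute
(WPM).  Repetitions, retraces, false starts, unintelligible material and
interruptions are coded inline and excluded from all counts; utterances that
are not complete, or consist wholly of repeated/retraced material, are dropped
before measurement.

Dialect
-------
* ``@id: <patient>`` and ``@duration: <seconds>`` metadata lines.
* Utterance lines, optionally prefixed ``*PAR:``.
* ``[/]`` flags the preceding word (or preceding ``<...>`` group) as a
  repetition; ``[//]`` as a retrace.
* ``&+frag`` is a false-start fragment, ``xxx`` unintelligible material.
* ``[and]`` marks a clause-joining "and" (an "and" connecting two independent
  clauses); plain ``and`` is treated as a phrase-internal conjunction.
* ``.``, ``?``, ``!`` terminate a complete utterance; ``+...`` (trailing off)
  and ``+/.`` (interruption) terminate an incomplete one.  Material at end of
  input without a terminator is incomplete.

Utterance segmentation applies the one-"and" rule: within a sentence, only one
clause-joining "and" is allowed, so a second clause-joining "and" starts a new
utterance (the split falls before that "and").

Morpheme counts are rule-based: one morpheme per free word plus one for each
recognised inflectional suffix (plural/possessive/3rd-person -s, past -ed,
progressive -ing, comparative -er / superlative -est, contracted auxiliaries),
with a bundled exception list of pseudo-suffixed words and an irregular
lexicon with explicit counts (irregular pasts are not decomposed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

TERMINATORS_COMPLETE = {".", "?", "!"}
TERMINATORS_INCOMPLETE = {"+...", "+/."}
FLAG_REPETITION = "repetition"
FLAG_RETRACE = "retrace"
FLAG_FALSE_START = "false_start"
FLAG_UNINTELLIGIBLE = "unintelligible"
FLAG_CLAUSE_AND = "clause_and"
_EXCLUDED_FLAGS = {FLAG_REPETITION, FLAG_RETRACE, FLAG_FALSE_START, FLAG_UNINTELLIGIBLE}


@dataclass
class Token:
    text: str
    flags: set[str] = field(default_factory=set)

    @property
    def countable(self) -> bool:
        return not (self.flags & _EXCLUDED_FLAGS)


@dataclass
class Utterance:
    tokens: list[Token]
    is_complete: bool = True

    def countable_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.countable]

    @property
    def wholly_excluded(self) -> bool:
        return len(self.tokens) > 0 and not self.countable_tokens()


@dataclass
class Transcript:
    patient_id: str
    utterances: list[Utterance]
    duration: float  # seconds of speech sample


@dataclass(frozen=True)
class SpeechMeasures:
    tokens: float
    types: float
    ttr: float
    morphemes: float
    mlu: float
    wpm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "tokens": self.tokens,
            "types": self.types,
            "ttr": self.ttr,
            "morphemes": self.morphemes,
            "mlu": self.mlu,
            "wpm": self.wpm,
        }


# ---------------------------------------------------------------------------
# tokenising and segmentation

_TERMINATOR_RE = re.compile(r"^(\+\.\.\.|\+/\.|[.?!])$")


def tokenize_line(line: str) -> list[Token]:
    """Turn one utterance line into flagged tokens plus terminator markers.

    Terminators are kept in the stream as bare ``Token`` objects whose text is
    the terminator symbol; :func:`segment_utterances` consumes them.
    """
    out: list[Token] = []
    open_group: int | None = None  # index where an unclosed <...> group starts
    closed_group: tuple[int, int] | None = None  # most recently closed group
    for raw in line.split():
        opens = raw.startswith("<") and raw != "<"
        closes = raw.endswith(">") and raw != ">"
        if raw == "<" or opens:
            if open_group is not None:
                raise ValueError(f"nested '<' in line: {line!r}")
            open_group = len(out)
            raw = raw[1:] if opens else ""
        if raw.endswith(">"):
            if open_group is None:
                raise ValueError(f"unbalanced '>' in line: {line!r}")
            word = raw[:-1]
            if word:
                out.append(Token(word.lower()))
            closed_group = (open_group, len(out))
            open_group = None
            continue
        if raw in ("[/]", "[//]"):
            flag = FLAG_REPETITION if raw == "[/]" else FLAG_RETRACE
            if closed_group is not None and closed_group[1] == len(out):
                lo, hi = closed_group
                targets = out[lo:hi]
            else:
                targets = out[-1:]
            closed_group = None
            if not targets:
                raise ValueError(f"{raw} with nothing to flag in line: {line!r}")
            for t in targets:
                t.flags.add(flag)
            continue
        if not raw:
            continue
        if _TERMINATOR_RE.match(raw):
            out.append(Token(raw))
            continue
        if raw == "[and]":
            out.append(Token("and", {FLAG_CLAUSE_AND}))
            continue
        if raw.startswith("&+"):
            out.append(Token(raw[2:], {FLAG_FALSE_START}))
            continue
        if raw == "xxx":
            out.append(Token("xxx", {FLAG_UNINTELLIGIBLE}))
            continue
        out.append(Token(raw.lower()))
    if open_group is not None:
        raise ValueError(f"unclosed '<...>' group in line: {line!r}")
    return out


def segment_utterances(tokens: list[Token]) -> list[Utterance]:
    """Split a flagged token stream into utterances.

    Explicit terminators always split.  Within a sentence, the one-"and" rule
    applies: a clause-joining "and" that would be the second one joining
    clauses inside the current utterance starts a new utterance instead (the
    "and" itself begins the new utterance).  A leading "and" carried over by
    such a split does not join two clauses within its own utterance, so it
    does not count against the rule there.
    """
    utterances: list[Utterance] = []
    current: list[Token] = []
    joining_ands = 0

    def flush(complete: bool):
        nonlocal current, joining_ands
        if current:
            utterances.append(Utterance(current, is_complete=complete))
        current = []
        joining_ands = 0

    for tok in tokens:
        if _TERMINATOR_RE.match(tok.text) and not tok.flags:
            flush(tok.text in TERMINATORS_COMPLETE)
            continue
        if FLAG_CLAUSE_AND in tok.flags:
            has_clause_before = any(
                FLAG_CLAUSE_AND not in t.flags for t in current
            )
            if has_clause_before:
                if joining_ands >= 1:
                    flush(True)  # split point inside a terminated sentence
                else:
                    joining_ands += 1
        current.append(tok)
    flush(False)
    return utterances


def filter_codable(utterances: list[Utterance]) -> list[Utterance]:
    """Keep only complete utterances with at least one countable token, and
    drop flagged (repeated/retraced/false-start/unintelligible) tokens inside
    them."""
    kept = []
    for utt in utterances:
        if not utt.is_complete or not utt.tokens:
            continue
        countable = utt.countable_tokens()
        if not countable:
            continue
        kept.append(Utterance(list(countable), is_complete=True))
    return kept


# ---------------------------------------------------------------------------
# morphology

@lru_cache(maxsize=1)
def _exceptions() -> frozenset[str]:
    text = resources.files("pcavbcm.data").joinpath("morpheme_exceptions.txt").read_text()
    words = {
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(words)


@lru_cache(maxsize=1)
def _irregulars() -> dict[str, int]:
    text = resources.files("pcavbcm.data").joinpath("irregular_lexicon.txt").read_text()
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        form, count = line.split("\t")
        table[form.strip().lower()] = int(count)
    return table


_CONTRACTED_SUFFIXES = ("n't", "'s", "'ve", "'ll", "'re", "'m", "'d")
_INFLECTIONS = ("ing", "est", "ed", "er", "es", "s")


def count_word_morphemes(word: str) -> int:
    """Morphemes in one surface word under the bundled rule set.

    Unknown words with no recognised suffix count as a single morpheme.
    """
    w = word.lower().strip()
    if not w:
        return 0
    irregular = _irregulars()
    if w in irregular:
        return irregular[w]
    if w in _exceptions():
        return 1
    count = 1
    for suf in _CONTRACTED_SUFFIXES:
        if w.endswith(suf) and len(w) > len(suf) + 1:
            count += 1
            w = w[: -len(suf)]
            break
    if w in _exceptions() or w in irregular:
        return count
    for suf in _INFLECTIONS:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if len(stem) >= 3 and not (suf == "s" and stem.endswith("s")):
                count += 1
                break
    return count


def count_morphemes(utterance: Utterance) -> int:
    """Total morphemes over the countable tokens of one utterance."""
    return sum(count_word_morphemes(t.text) for t in utterance.countable_tokens())


# ---------------------------------------------------------------------------
# measures

def speech_measures(transcript: Transcript) -> SpeechMeasures:
    """Compute the six fluency measures for one transcript.

    All measures are zero for an empty (or wholly excluded) transcript; a
    positive token count with a non-positive duration is an error because WPM
    is undefined.
    """
    kept = filter_codable(transcript.utterances)
    words = [t.text.lower() for u in kept for t in u.tokens]
    T = len(words)
    if T == 0:
        return SpeechMeasures(0, 0, 0.0, 0, 0.0, 0.0)
    if transcript.duration <= 0:
        raise ValueError(
            f"{transcript.patient_id}: positive duration required to compute WPM"
        )
    types = len(set(words))
    morphemes = sum(count_morphemes(u) for u in kept)
    return SpeechMeasures(
        tokens=T,
        types=types,
        ttr=types / T,
        morphemes=morphemes,
        mlu=morphemes / len(kept),
        wpm=60.0 * T / transcript.duration,
    )


def read_transcript(text: str, patient_id: str | None = None) -> Transcript:
    """Parse a transcript from its plain-text dialect form."""
    pid = patient_id or "unknown"
    duration = 0.0
    tokens: list[Token] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("%"):
            continue
        if line.lower().startswith("@id:"):
            pid = line.split(":", 1)[1].strip()
            continue
        if line.lower().startswith("@duration:"):
            duration = float(line.split(":", 1)[1].strip())
            continue
        if line.startswith("@"):
            continue
        if line.startswith("*"):
            line = line.split(":", 1)[1].strip()
        tokens.extend(tokenize_line(line))
    return Transcript(pid, segment_utterances(tokens), duration)


def read_transcript_file(path) -> Transcript:
    with open(path, encoding="utf-8") as fh:
        return read_transcript(fh.read())


def measures_table(transcripts: list[Transcript]) -> pd.DataFrame:
    """Per-patient raw measures table (one row per transcript)."""
    rows = {t.patient_id: speech_measures(t).as_dict() for t in transcripts}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# percent conversion

def percent_normalize(
    raw: pd.DataFrame, mode: str = "cohort_max", maxima: dict | pd.Series | None = None
) -> pd.DataFrame:
    """Convert raw scores to percent of the column maximum.

    ``cohort_max`` divides by the observed column maximum (so the best
    participant scores 100 by construction); ``test_max`` divides by a
    supplied per-column maximum.  Values must be non-negative.
    """
    vals = raw.to_numpy(float) if isinstance(raw, pd.DataFrame) else np.asarray(raw, float)
    if (vals < 0).any():
        raise ValueError("percent conversion requires non-negative scores")
    if mode == "cohort_max":
        denom = vals.max(axis=0)
        if (denom == 0).any():
            j = int(np.flatnonzero(denom == 0)[0])
            name = raw.columns[j] if isinstance(raw, pd.DataFrame) else j
            raise ValueError(f"all-zero column {name!r} has no cohort maximum")
    elif mode == "test_max":
        if maxima is None:
            raise ValueError("test_max mode requires per-column maxima")
        if isinstance(raw, pd.DataFrame):
            denom = np.asarray([maxima[c] for c in raw.columns], float)
        else:
            denom = np.asarray(maxima, float)
        if (denom <= 0).any():
            raise ValueError("supplied maxima must be positive")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = 100.0 * vals / denom
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out
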