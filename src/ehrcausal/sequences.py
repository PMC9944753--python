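"""Token sequences for the EHR transformer.

A patient's pre-entry history becomes an ordered token sequence: a CLS
token, a sex token and a baseline smoking token, followed by dx/rx code
tokens grouped into day-level visits separated by SEP. Each token carries
an age (integer years at the event day), a segment index (visit parity)
and a position index (visit order), mirroring the standard coded-EHR
transformer input representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import PatientRecord
from .config import DAYS_PER_YEAR

PAD, MASK, UNK, SEP, CLS = "[PAD]", "[MASK]", "[UNK]", "[SEP]", "[CLS]"
SPECIALS = (PAD, MASK, UNK, SEP, CLS)
SEX_TOKENS = ("SEX_F", "SEX_M")
SMOKING_TOKENS = ("SMOKE_never", "SMOKE_former", "SMOKE_current", "SMOKE_unknown")

IGNORE_LABEL = -100
MAX_AGE = 119


@dataclass
class Vocabulary:
    """Contiguous token->index map: specials, sex, smoking, then codes
    in lexicographic order."""

    index: dict[str, int]
    code_ids: frozenset[int]

    @classmethod
    def from_codes(cls, codes) -> "Vocabulary":
        ordered = list(SPECIALS) + list(SEX_TOKENS) + list(SMOKING_TOKENS) \
            + sorted(set(codes))
        index = {tok: i for i, tok in enumerate(ordered)}
        n_head = len(SPECIALS) + len(SEX_TOKENS) + len(SMOKING_TOKENS)
        return cls(index=index, code_ids=frozenset(range(n_head, len(ordered))))

    @classmethod
    def from_records(cls, records: list[PatientRecord]) -> "Vocabulary":
        return cls.from_codes(c for r in records for _, c, _ in r.events)

    def __len__(self) -> int:
        return len(self.index)

    def encode_code(self, code: str) -> int:
        return self.index.get(code, self.index[UNK])

    def __getitem__(self, token: str) -> int:
        return self.index[token]

    def is_maskable(self, token_id: int) -> bool:
        """Code tokens (and UNK standing in a code slot) can be masked."""
        return token_id in self.code_ids or token_id == self.index[UNK]


@dataclass
class TokenSequence:
    """Aligned token / age / segment / position lists plus mask labels."""

    tokens: list[int]
    ages: list[int]
    segments: list[int]
    positions: list[int]
    mem_labels: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.mem_labels:
            self.mem_labels = [IGNORE_LABEL] * len(self.tokens)
        lens = {len(self.tokens), len(self.ages), len(self.segments),
                len(self.positions), len(self.mem_labels)}
        if len(lens) != 1:
            raise ValueError("aligned lists must have equal length")

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_history(patient: PatientRecord, entry_day: int,
                     vocab: Vocabulary, max_len: int) -> TokenSequence:
    """Tokenize all coded events strictly before ``entry_day``.

    Events are grouped into day-level visits, visits are separated by SEP,
    and the sequence is truncated from the front (oldest events dropped)
    to ``max_len`` tokens while the CLS/sex/smoking header is always kept.
    """
    smoking = patient.smoking if patient.smoking in ("never", "former", "current") \
        else "unknown"
    pre_days = [d for d, _, _ in patient.events if d < entry_day]
    # header carries the age at the earliest visit so ages are
    # non-decreasing along the sequence
    first_day = min(pre_days) if pre_days else entry_day
    age_first = min(max(int(patient.age_at(first_day)), 0), MAX_AGE)
    header = [vocab[CLS], vocab[f"SEX_{patient.sex}"], vocab[f"SMOKE_{smoking}"]]
    tokens = list(header)
    ages = [age_first] * 3
    segments = [0] * 3
    positions = [0] * 3

    pre = [(d, c) for d, c, _ in patient.events if d < entry_day]
    pre.sort(key=lambda t: (t[0], t[1]))
    visit_idx = 0
    last_day = None
    for day, code in pre:
        age = min(max(int(patient.age_at(day)), 0), MAX_AGE)
        if last_day is not None and day != last_day:
            tokens.append(vocab[SEP])
            ages.append(min(max(int(patient.age_at(last_day)), 0), MAX_AGE))
            segments.append(visit_idx % 2)
            positions.append(visit_idx + 1)
            visit_idx += 1
        tokens.append(vocab.encode_code(code))
        ages.append(age)
        segments.append(visit_idx % 2)
        positions.append(visit_idx + 1)
        last_day = day

    if len(tokens) > max_len:
        keep = max_len - 3
        body = list(zip(tokens[3:], ages[3:], segments[3:], positions[3:]))[-keep:]
        while body and body[0][0] == vocab[SEP]:
            body = body[1:]
        tokens = header + [t for t, *_ in body]
        ages = ages[:3] + [a for _, a, *_ in body]
        segments = [0] * 3 + [s for _, _, s, _ in body]
        positions = [0] * 3 + [p for *_, p in body]
    return TokenSequence(tokens=tokens, ages=ages, segments=segments,
                         positions=positions)


def mask_tokens(seq: TokenSequence, mask_rate: float, seed: int,
                vocab: Vocabulary) -> TokenSequence:
    """Masked-EHR-modeling corruption.

    Each code token is independently selected with probability
    ``mask_rate``; a selected token is replaced by MASK (80%), by a random
    code token (10%) or kept (10%), and its original index is recorded in
    ``mem_labels``. Specials and the header are never selected.
    """
    rng = np.random.default_rng(seed)
    code_list = sorted(vocab.code_ids)
    tokens = list(seq.tokens)
    labels = [IGNORE_LABEL] * len(tokens)
    for i, tok in enumerate(tokens):
        if i < 3 or not vocab.is_maskable(tok):
            continue
        if rng.random() < mask_rate:
            labels[i] = tok
            u = rng.random()
            if u < 0.8:
                tokens[i] = vocab[MASK]
            elif u < 0.9 and code_list:
                tokens[i] = int(code_list[rng.integers(len(code_list))])
    return TokenSequence(tokens=tokens, ages=list(seq.ages),
                         segments=list(seq.segments),
                         positions=list(seq.positions), mem_labels=labels)


def pad_batch(seqs: list[TokenSequence], pad_id: int = 0) -> dict:
    """Stack sequences into padded integer arrays plus a validity mask."""
    T = max(len(s) for s in seqs)
    n = len(seqs)
    out = {k: np.zeros((n, T), dtype=np.int64)
           for k in ("tokens", "ages", "segments", "positions")}
    out["mem_labels"] = np.full((n, T), IGNORE_LABEL, dtype=np.int64)
    out["attn"] = np.zeros((n, T), dtype=bool)
    for i, s in enumerate(seqs):
        L = len(s)
        out["tokens"][i, :L] = s.tokens
        out["ages"][i, :L] = s.ages
        out["segments"][i, :L] = s.segments
        out["positions"][i, :L] = s.positions
        out["mem_labels"][i, :L] = s.mem_labels
        out["attn"][i, :L] = True
    return out
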