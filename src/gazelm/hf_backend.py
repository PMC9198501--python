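"""Optional transformer backend (GPT-2-style causal LM).

Satisfies the :class:`gazelm.predictability.LMAdapter` contract on top of a
Hugging Face causal language model — the reference backend is the released
117M-parameter GPT-2 base model (12-layer, 768-hidden), used as published
with no fine-tuning, on CPU. ``transformers`` and ``torch`` are deliberately
optional (extra ``gazelm[transformer]``); everything in the core package and
test suite runs on the table-driven toy backend instead.

Conventions: a word is tokenized with a leading space unless passage-initial
(the byte-pair vocabulary distinguishes word-initial pieces by the space
marker); contextual embeddings come from the final hidden layer, mean-pooled
over the word's pieces, computed in the identical preceding context for
prediction and target.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["TransformerLM"]


class TransformerLM:
    """Causal-LM adapter over a Hugging Face model (lazy imports)."""

    def __init__(self, model_name: str = "gpt2", device: str = "cpu"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModelForCausalLM, AutoTokenizer
        except ImportError as e:  # pragma: no cover - optional dependency
            raise ImportError(
                "the transformer backend needs the optional dependencies "
                "torch and transformers (pip install 'gazelm[transformer]')"
            ) from e
        import torch

        self._torch = torch
        self._tok = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModelForCausalLM.from_pretrained(model_name).to(device)
        self._model.eval()
        self._device = device
        #: Model context window; longer contexts raise rather than truncate.
        self.max_context = int(self._model.config.n_positions)

    @property
    def vocab_size(self) -> int:
        return int(self._model.config.vocab_size)

    def tokenize(self, word: str, *, initial: bool = False) -> list[int]:
        text = word if initial else " " + word
        return self._tok.encode(text, add_special_tokens=False)

    def piece(self, token_id: int) -> str:
        return self._tok.decode([token_id])

    def is_word_initial(self, token_id: int) -> bool:
        raw = self._tok.convert_ids_to_tokens(token_id)
        # GPT-2 byte-pair pieces mark a preceding space with U+0120.
        return raw.startswith("Ġ")

    def logits(self, context_ids: Sequence[int]) -> np.ndarray:
        torch = self._torch
        if len(context_ids) > self.max_context:
            raise ValueError(
                f"context of {len(context_ids)} pieces exceeds the model window "
                f"of {self.max_context}"
            )
        with torch.no_grad():
            ids = torch.tensor([list(context_ids)], device=self._device)
            out = self._model(ids)
        return out.logits[0, -1].cpu().numpy().astype(float)

    def embed_word(self, context_ids: Sequence[int], word: str) -> np.ndarray:
        torch = self._torch
        word_ids = self.tokenize(word, initial=not context_ids)
        ids = list(context_ids) + word_ids
        with torch.no_grad():
            out = self._model(
                torch.tensor([ids], device=self._device), output_hidden_states=True
            )
        # Final hidden layer, mean-pooled over the word's pieces.
        hidden = out.hidden_states[-1][0, len(context_ids):]
        return hidden.mean(dim=0).cpu().numpy().astype(float)
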