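"""End-to-end orchestration: configuration, I/O and the full analysis run.

A :class:`RunConfig` fully determines a run — every random draw flows from
one of its named seeds, so two runs with the same config produce identical
outputs.  The run builds the stimulus design, simulates (or ingests) a
response matrix, computes reliabilities, fits the factor / combination /
n-gram / string-distortion models, runs the decoders and the conjunction
error analysis, and writes a summary JSON plus CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, error_analysis, separability, synthetic_neurons
from .stimuli import StimulusSet, build_stimulus_set
from .synthetic_neurons import ResponseMatrix

__all__ = ["RunConfig", "run_full_experiment", "read_response_csv",
           "write_response_csv"]


@dataclass
class RunConfig:
    """Serializable description of one full analysis run."""

    out_dir: str = "neurosep_run"
    seeds: dict = field(default_factory=lambda: {
        "stimuli": 0, "population": 1, "sampling": 2, "decoding": 3, "shuffle": 4,
    })
    stimuli: dict = field(default_factory=lambda: {
        "include_hard": False,
    })
    population: dict = field(default_factory=lambda: {
        "type": "separable", "n": 100, "kind_policy": "mixed",
        "attribute_rule": "multiplicative", "string_rule": "sum",
        "normalize": True, "match_reliability": 0.5,
    })
    fit: dict = field(default_factory=lambda: {
        "epsilon": None, "letter_matrix": "predicted",
    })
    decode: dict = field(default_factory=lambda: {
        "folds": 5, "iterations": 50, "pca_variance": 0.95,
    })
    responses_csv: str | None = None  # ingest instead of simulating

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_response_csv(rm: ResponseMatrix, path) -> None:
    """Tidy CSV: neuron_id, stimulus_id, repetition (1-based), rate_hz."""
    n, s, r = rm.rates.shape
    df = pd.DataFrame({
        "neuron_id": np.repeat(rm.neuron_ids, s * r),
        "stimulus_id": np.tile(np.repeat([d.stimulus_id for d in rm.stimulus_set], r), n),
        "repetition": np.tile(np.arange(1, r + 1), n * s),
        "rate_hz": rm.rates.ravel(),
    })
    df.to_csv(path, index=False)


def read_response_csv(path, stimulus_set: StimulusSet) -> ResponseMatrix:
    """Read a tidy response CSV back into a (neurons, stimuli, reps) matrix.

    Stimulus ids must resolve against the stimulus set; negative rates and
    missing columns are rejected with explicit errors.
    """
    df = pd.read_csv(path)
    required = {"neuron_id", "stimulus_id", "repetition", "rate_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response CSV is missing columns: {sorted(missing)}")
    neg = np.flatnonzero(df["rate_hz"].to_numpy() < 0)
    if len(neg):
        raise ValueError(f"negative rate at CSV row {int(neg[0]) + 2}")
    known = {d.stimulus_id for d in stimulus_set}
    for sid in df["stimulus_id"]:
        if sid not in known:
            raise ValueError(f"stimulus id not in manifest: {sid!r}")
    neurons = list(dict.fromkeys(df["neuron_id"]))
    reps = sorted(df["repetition"].unique())
    rates = np.zeros((len(neurons), len(stimulus_set), len(reps)))
    n_idx = {v: i for i, v in enumerate(neurons)}
    s_idx = {d.stimulus_id: i for i, d in enumerate(stimulus_set)}
    r_idx = {v: i for i, v in enumerate(reps)}
    rates[df["neuron_id"].map(n_idx), df["stimulus_id"].map(s_idx),
          df["repetition"].map(r_idx)] = df["rate_hz"]
    return ResponseMatrix(rates, stimulus_set, [str(x) for x in neurons])


def _build_population(cfg: RunConfig, sset: StimulusSet):
    p = cfg.population
    if p["type"] == "separable":
        return synthetic_neurons.make_separable_population(
            p["n"], kind_policy=p.get("kind_policy", "mixed"),
            attribute_rule=p.get("attribute_rule", "multiplicative"),
            string_rule=p.get("string_rule", "sum"),
            normalize=p.get("normalize", True),
            seed=cfg.seeds["population"],
        )
    if p["type"].startswith("conj"):
        bigrams = sset.provenance.get("ngram_strings", {}).get("2")
        return synthetic_neurons.make_conjunction_population(
            int(p["type"][-1]), p["n"], seed=cfg.seeds["population"],
            bigrams=bigrams)
    raise ValueError(f"unknown population type: {p['type']!r}")


def run_full_experiment(config: RunConfig) -> dict:
    """Run every stage of the analysis and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {"config": dataclasses.asdict(config)}

    sset = build_stimulus_set(seed=config.seeds["stimuli"],
                              include_hard=config.stimuli.get("include_hard", False))
    sset.save_manifest(out / "stimuli.json")
    log.append(f"stimuli: {len(sset)} descriptors")

    if config.responses_csv:
        rm = read_response_csv(config.responses_csv, sset)
        log.append(f"ingested responses from {config.responses_csv}")
    else:
        population = _build_population(config, sset)
        target = config.population.get("match_reliability")
        if target:
            population, info = synthetic_neurons.match_reliability(
                population, target, sset, seed=config.seeds["sampling"])
            log.append(f"reliability matching: {int(info['unreachable'].sum())} unreachable")
        rm = synthetic_neurons.sample_poisson(population, sset,
                                              seed=config.seeds["sampling"])
    write_response_csv(rm, out / "responses.csv")

    rm_letters = rm.select("single_letter")
    rm_ngrams = rm.select("ngram")

    rel_letters = separability.split_half_reliability(rm_letters)
    rel_ngrams = separability.split_half_reliability(rm_ngrams)

    fits = {}
    for rule in ("additive", "multiplicative"):
        fits[rule] = separability.fit_factor_model(rm_letters, rule)
    comb = separability.fit_combination_model(rm_letters)
    if config.fit.get("letter_matrix", "predicted") == "raw":
        letter_grid = separability.raw_letter_matrix(rm)
    else:
        letter_grid = np.stack(
            [separability.predicted_letter_matrix(f, clip_at_zero=True)
             for f in fits["multiplicative"]])
    ngram_fits = {
        "additive": separability.fit_ngram_additive(rm_ngrams, letter_grid),
        "multiplicative": separability.fit_ngram_multiplicative(
            rm_ngrams, letter_grid, epsilon=config.fit.get("epsilon")),
    }
    sd_fits = {rule: separability.fit_string_distortion_model(rm_ngrams, rule)
               for rule in ("additive", "multiplicative")}
    shuffled = separability.shuffle_control(rm_ngrams, letter_grid,
                                            seed=config.seeds["shuffle"])

    table = pd.DataFrame({
        "neuron_id": rm.neuron_ids,
        "reliability_letters": rel_letters.r,
        "reliability_ngrams": rel_ngrams.r,
        "r_factor_add": [f.cv_correlation for f in fits["additive"]],
        "r_factor_mult": [f.cv_correlation for f in fits["multiplicative"]],
        "r_comb": [f.cv_correlation for f in comb],
        "r_ngram_add": [f.cv_correlation for f in ngram_fits["additive"]],
        "r_ngram_mult": [f.cv_correlation for f in ngram_fits["multiplicative"]],
        "r_stringdist_add": [f.cv_correlation for f in sd_fits["additive"]],
        "r_stringdist_mult": [f.cv_correlation for f in sd_fits["multiplicative"]],
        "r_ngram_shuffled": [f.cv_correlation for f in shuffled],
    })
    table["norm_factor_mult"] = separability.normalized_model_correlation(
        table["r_factor_mult"], table["reliability_letters"])
    table["norm_ngram_add"] = separability.normalized_model_correlation(
        table["r_ngram_add"], table["reliability_ngrams"])
    table.to_csv(out / "model_fits.csv", index=False)

    letter_labels = [d.letters for d in rm_letters.stimulus_set]
    dec_letters = decoding.decode_letter_identity(
        rm_letters.means(), letter_labels,
        folds=config.decode["folds"], iterations=config.decode["iterations"],
        seed=config.seeds["decoding"])
    dec_slots = decoding.decode_characters_by_slot(
        rm_ngrams.means(), decoding.slot_labels(rm_ngrams.stimulus_set),
        folds=config.decode["folds"], pca_variance=config.decode["pca_variance"],
        seed=config.seeds["decoding"])

    err = error_analysis.compute_ngram_errors(rm_ngrams, letter_grid)
    err_test = error_analysis.conjunction_error_test(err, base_length=2)

    masked = rel_letters.mask
    summary.update({
        "n_stimuli": len(sset),
        "n_neurons": rm.n_neurons,
        "neurons_included_letters": int(rel_letters.mask.sum()),
        "neurons_excluded_letters": int((~rel_letters.mask).sum()),
        "neurons_included_ngrams": int(rel_ngrams.mask.sum()),
        "neurons_excluded_ngrams": int((~rel_ngrams.mask).sum()),
        "median_r_factor_add": float(np.nanmedian(table["r_factor_add"][masked])),
        "median_r_factor_mult": float(np.nanmedian(table["r_factor_mult"][masked])),
        "factor_mult_vs_add_p": separability.signrank_p(
            table["r_factor_mult"][masked], table["r_factor_add"][masked]),
        "median_r_ngram_add": float(np.nanmedian(table["r_ngram_add"][rel_ngrams.mask])),
        "median_r_ngram_mult": float(np.nanmedian(table["r_ngram_mult"][rel_ngrams.mask])),
        "ngram_add_vs_mult_p": separability.signrank_p(
            table["r_ngram_add"][rel_ngrams.mask], table["r_ngram_mult"][rel_ngrams.mask]),
        "mean_r_ngram_shuffled": float(np.nanmean(table["r_ngram_shuffled"])),
        "letter_decoding_accuracy": dec_letters.mean_accuracy,
        "slot_decoding_accuracy": dec_slots.mean_accuracy,
        "error_test_p_by_length": {str(k): v["p"] for k, v in err_test.items()},
        "log": log,
    })
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
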