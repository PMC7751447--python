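"""End-to-end scale-development pipeline orchestration.

Stages, in instrument-development order: content-validity screening (when
expert ratings are supplied) → CTT statistics per language → 2PL
calibration per language → mean/sigma equating of every non-reference
form onto the reference → likelihood-ratio DIF tests against the
reference → nested stratified short-form selection driven by the
reference language → reliability summaries for every form → convergent
validity correlations (when covariates exist) → intervention-sensitivity
table (when arm/timepoint metadata exists).  Every artifact is written
under the output directory as CSV/JSON with the config hash embedded;
identical config + seed reproduces all outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .bank import ItemBank, read_item_bank
from .content_validity import compute_cvi
from .ctt import cronbach_alpha, item_statistics, stats_to_frame, summarize_scale
from .dif import dif_test, dif_to_frame
from .equate import difficulty_separation_report, mean_sigma_equate
from .irt import IRTConfig, fit_2pl, params_to_frame
from .responses import ResponseMatrix, read_response_matrix
from .short_form import (
    allocate_quotas,
    fit_mean_curve,
    multi_language_review,
    select_items,
)
from .validity import convergent_validity, sensitivity_analysis

logger = logging.getLogger("realmkit")


@dataclass
class PipelineConfig:
    item_bank_path: str | None = None
    responses_path: str | None = None
    ratings_path: str | None = None
    reference_language: str = "en"
    form_lengths: tuple[int, ...] = (40, 20)
    irt: IRTConfig = field(default_factory=IRTConfig)
    dif_alpha: float = 0.05
    dif_adjustment: str = "benjamini-hochberg"
    p_range: tuple[float, float] | None = (5.0, 95.0)
    cvi_threshold: float = 0.80
    seed: int = 0
    out_dir: str = "realmkit_out"

    def __post_init__(self) -> None:
        lengths = tuple(self.form_lengths)
        if list(lengths) != sorted(lengths, reverse=True) or len(set(lengths)) != len(lengths):
            raise ValidationError(f"form lengths must be strictly decreasing: {lengths}")
        self.form_lengths = lengths

    def digest(self) -> str:
        # hash the analytic configuration only, not where inputs/outputs live
        skip = {"out_dir", "item_bank_path", "responses_path", "ratings_path"}
        payload = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self).items()
                if not isinstance(v, IRTConfig) and k not in skip
            }
            | {"irt": vars(self.irt)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    bank: ItemBank | None = None,
    responses: ResponseMatrix | None = None,
    ratings: pd.DataFrame | None = None,
) -> dict:
    """Run all applicable stages; returns a dict of in-memory artifacts.

    Inputs may be passed directly or via paths in the config.  Stage
    failures raise with the stage name; artifacts produced before the
    failure are already on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    bundle: dict = {"config_digest": digest}

    def _write_json(name: str, payload) -> None:
        payload = dict(payload)
        payload["config_digest"] = digest
        with open(out / name, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)

    def _write_csv(name: str, df: pd.DataFrame) -> None:
        df = df.copy()
        df.attrs = {}
        df.to_csv(out / name, index=False, encoding="utf-8", float_format="%.10g")

    stage = "load"
    try:
        if bank is None:
            if config.item_bank_path is None:
                raise ValidationError("no item bank given")
            bank = read_item_bank(config.item_bank_path)
        if responses is None:
            if config.responses_path is None:
                raise ValidationError("no response matrix given")
            responses = read_response_matrix(config.responses_path)
        responses.validate_against(bank)
        if ratings is None and config.ratings_path is not None:
            ratings = pd.read_csv(config.ratings_path)
        if config.reference_language not in bank.languages:
            raise ValidationError(
                f"reference language {config.reference_language!r} not in bank"
            )

        if ratings is not None:
            stage = "content_validity"
            cvi = compute_cvi(ratings, threshold=config.cvi_threshold)
            bundle["cvi"] = cvi
            _write_csv("cvi_report.csv", cvi.to_frame())

        languages = [
            lang for lang in bank.languages
            if (responses.meta["language"] == lang).any()
        ]
        stratum_of = bank.stratum_of()

        stage = "ctt"
        stats_by_lang, alpha_by_lang = {}, {}
        all_stats = []
        for lang in languages:
            sub = responses.subset(language=lang)
            stats = item_statistics(sub, language=lang)
            stats_by_lang[lang] = stats
            alpha_by_lang[lang] = cronbach_alpha(sub)
            all_stats.extend(stats)
        bundle["item_stats"] = stats_by_lang
        _write_csv("item_stats.csv", stats_to_frame(all_stats))

        stage = "irt"
        params_by_lang, traces = {}, {}
        for lang in languages:
            sub = responses.subset(language=lang)
            params, trace = fit_2pl(sub, language=lang, config=config.irt)
            params_by_lang[lang] = params
            traces[lang] = trace
            logger.info("2PL %s: %d iters, converged=%s", lang, trace.n_iter,
                        trace.converged)
        bundle["item_params"] = params_by_lang
        bundle["fit_traces"] = traces
        _write_json(
            "fit_trace.json",
            {
                lang: {"n_iter": t.n_iter, "converged": t.converged,
                       "loglik": t.loglik[-1] if t.loglik else None}
                for lang, t in traces.items()
            },
        )

        stage = "equate"
        ref = config.reference_language
        equated = {ref: params_by_lang[ref]}
        transforms = {}
        for lang in languages:
            if lang == ref:
                continue
            common = _common_usable(params_by_lang[lang], params_by_lang[ref])
            tr, transformed = mean_sigma_equate(
                [p for p in params_by_lang[lang] if p.item_id in common],
                [p for p in params_by_lang[ref] if p.item_id in common],
            )
            transforms[lang] = tr
            equated[lang] = transformed
        bundle["equating"] = transforms
        _write_json(
            "equating.json",
            {lang: {"A": tr.A, "B": tr.B, "reference": ref}
             for lang, tr in transforms.items()},
        )
        params_frame = pd.concat(
            [params_to_frame(equated[lang]) for lang in equated], ignore_index=True
        )
        _write_csv("item_params.csv", params_frame)

        stage = "separation"
        separation = {
            lang: difficulty_separation_report(equated[lang], stratum_of)
            for lang in equated
        }
        bundle["separation"] = separation
        _write_json(
            "separation.json",
            {lang: {"index": rep.separation_index} for lang, rep in separation.items()},
        )

        stage = "dif"
        dif_results = {}
        ref_matrix = responses.subset(language=ref)
        for lang in languages:
            if lang == ref:
                continue
            foc_matrix = responses.subset(language=lang)
            dif_results[lang] = dif_test(
                ref_matrix,
                foc_matrix,
                alpha=config.dif_alpha,
                adjustment=config.dif_adjustment,
                config=config.irt,
            )
        bundle["dif"] = dif_results
        if dif_results:
            frames = []
            for lang, res in dif_results.items():
                f = dif_to_frame(res)
                f.insert(0, "focal_language", lang)
                frames.append(f)
            _write_csv("dif_report.csv", pd.concat(frames, ignore_index=True))

        stage = "short_form"
        ref_stats = stats_by_lang[ref]
        curve = fit_mean_curve(ref_stats)
        selections = []
        parent = None
        # quotas always derive from the full bank's stratum sizes, so every
        # nested form preserves the original difficulty distribution
        for L in config.form_lengths:
            quotas = allocate_quotas(bank.stratum_counts(), L)
            sel = select_items(
                ref_stats, curve, quotas, bank,
                p_range=config.p_range, parent=parent, language=ref,
            )
            selections.append(sel)
            parent = sel
        bundle["selections"] = selections
        bundle["curve"] = curve
        _write_json(
            "selection.json",
            {
                f"form_{sel.form_length}": {
                    "parent": sel.parent_length,
                    "language": sel.language,
                    "selected": sel.selected,
                    "flags": sorted(sel.flags),
                }
                for sel in selections
            },
        )
        other_stats = {lang: stats_by_lang[lang] for lang in languages if lang != ref}
        if other_stats:
            review = multi_language_review(selections[-1], other_stats)
            bundle["review"] = review
            _write_csv("multi_language_review.csv", review)

        stage = "reliability"
        reports = []
        forms = {f"form_{len(bank)}": bank.item_ids}
        for sel in selections:
            forms[f"form_{sel.form_length}"] = sel.selected_ids
        rel_payload = {}
        for form_name, ids in forms.items():
            for lang in languages:
                sub = responses.subset(language=lang, items=ids)
                alpha = cronbach_alpha(sub)
                stats = item_statistics(sub, language=lang)
                rep = summarize_scale(stats, alpha, n=sub.n_persons, language=lang)
                reports.append((form_name, rep))
                rel_payload[f"{form_name}:{lang}"] = {
                    "k": rep.k, "n": rep.n, "alpha": rep.alpha,
                    "r_it_median": rep.r_it_median, "r_it_range": rep.r_it_range,
                    "p_median": rep.p_median, "p_range": rep.p_range,
                }
        bundle["reliability"] = reports
        _write_json("reliability.json", rel_payload)

        cov_cols = responses.covariate_columns()
        if cov_cols:
            stage = "validity"
            frames = []
            for lang in languages:
                sub = responses.subset(language=lang)
                table = {}
                for form_name, ids in forms.items():
                    table[form_name] = sub.percent_scores(ids)
                for c in cov_cols:
                    table[c.removeprefix("cov_")] = sub.meta[c].to_numpy(dtype=float)
                vf = convergent_validity(pd.DataFrame(table))
                vf.insert(0, "language", lang)
                frames.append(vf)
            validity = pd.concat(frames, ignore_index=True)
            bundle["validity"] = validity
            _write_csv("validity_matrix.csv", validity)

        has_long = (responses.meta["timepoint"] != "none").any()
        if has_long:
            stage = "sensitivity"
            long_rows = responses.meta["timepoint"] != "none"
            frames = []
            for form_name, ids in forms.items():
                scores = pd.DataFrame(
                    {
                        "person_id": responses.meta.loc[long_rows, "person_id"],
                        "arm": responses.meta.loc[long_rows, "arm"],
                        "timepoint": responses.meta.loc[long_rows, "timepoint"],
                        "percent": responses.percent_scores(ids)[long_rows.to_numpy()],
                    }
                )
                tab = sensitivity_analysis(scores)
                tab.insert(0, "form", form_name)
                frames.append(tab)
            sens = pd.concat(frames, ignore_index=True)
            bundle["sensitivity"] = sens
            _write_csv("sensitivity_table.csv", sens)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    return bundle


def _common_usable(p1, p2):
    ok1 = {p.item_id for p in p1 if "excluded_degenerate" not in p.flags and np.isfinite(p.b)}
    ok2 = {p.item_id for p in p2 if "excluded_degenerate" not in p.flags and np.isfinite(p.b)}
    return ok1 & ok2


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    return str(obj)
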