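"""Menu semantics, word prediction, planning, and the simulated user."""

from collections import deque

import pytest
from hypothesis import given, settings, strategies as st

from spellersim.speller_fsm import (COMMAND_TEMPLATES, MENU_CONFIRMATION,
                                    MENU_IC, MENU_NC, MENU_SPELLING, Speller,
                                    SpellerState, Stage, TaskSpec, WordCorpus,
                                    build_menu_catalog, completed_stages,
                                    default_tasks, packaged_corpus,
                                    plan_minimum_actions, predict_words,
                                    simulated_user_policy, task4_fixed_part)


@pytest.fixture(scope="module")
def catalog():
    return build_menu_catalog()


class TestMenuCatalog:
    @pytest.mark.parametrize("menu,dummies", [
        ("nc", 48), ("ic", 39), ("spelling", 0), ("confirmation", 47)])
    def test_dummy_counts(self, catalog, menu, dummies):
        layout = getattr(catalog, menu)
        assert layout.n_dummies == dummies
        assert sum(len(r) for r in layout.grid) == 49

    def test_ic_menu_has_exactly_ten_commands(self, catalog):
        assert 49 - catalog.ic.n_dummies == 10

    def test_every_send_prefix_ends_with_a_space(self):
        for cmd in ("Send WA", "Send TG", "Send SMS", "Send Mail", "Reply"):
            assert COMMAND_TEMPLATES[cmd].endswith(" ")

    def test_spelling_menu_covers_letters_and_digits(self, catalog):
        items = {c for row in catalog.spelling.grid for c in row}
        for ch in "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789":
            assert ch in items


class TestSelectionSemantics:
    def test_nc_dummy_is_a_no_op(self, speller):
        state = speller.initial_state()
        new, eff = speller.apply_selection(state, "X")
        assert new == state and eff.spoken == ()

    def test_send_wa_writes_prefix_and_opens_spelling(self, speller):
        state, _ = speller.apply_selection(speller.initial_state(), "IC")
        state, _ = speller.apply_selection(state, "Send WA")
        assert state.menu == MENU_SPELLING
        assert state.sentence == "Ok Google, send a WhatsApp to "
        assert state.spelled == ""

    def test_read_command_speaks_and_returns_to_nc(self, speller):
        state, _ = speller.apply_selection(speller.initial_state(), "IC")
        state, eff = speller.apply_selection(state, "Read WA")
        assert eff.spoken == ("Ok Google, read my WhatsApp messages",)
        assert state.menu == MENU_NC and state.sentence == ""

    def test_ok_then_back_keeps_the_sentence(self, speller):
        state = self._spelling_state(speller, "HOLA")
        state, _ = speller.apply_selection(state, "OK")
        assert state.menu == MENU_CONFIRMATION and state.pending == "ok"
        state, _ = speller.apply_selection(state, "Back")
        assert state.menu == MENU_SPELLING and state.spelled == "HOLA"

    def test_confirm_ok_speaks_full_sentence_and_clears(self, speller):
        state = self._spelling_state(speller, "HOLA")
        state, _ = speller.apply_selection(state, "OK")
        state, eff = speller.apply_selection(state, "Confirm")
        assert eff.spoken == ("Ok Google, send a WhatsApp to HOLA",)
        assert state.menu == MENU_NC and state.sentence == ""

    def test_confirm_ic_discards_sentence_into_ic(self, speller):
        state = self._spelling_state(speller, "HOLA")
        state, _ = speller.apply_selection(state, "IC")
        assert state.pending == "ic"
        state, eff = speller.apply_selection(state, "Confirm")
        assert state.menu == MENU_IC and state.sentence == "" and eff.spoken == ()

    def test_cancel_speaks_and_clears(self, speller):
        state, _ = speller.apply_selection(speller.initial_state(), "IC")
        state, eff = speller.apply_selection(state, "Cancel")
        assert eff.spoken == ("Ok Google, cancel",)
        assert state.menu == MENU_NC

    def test_delete_on_empty_buffer_is_a_no_op(self, speller):
        state = self._spelling_state(speller, "")
        new, _ = speller.apply_selection(state, "Del.")
        assert new == state
        new, _ = speller.apply_selection(state, "Del. W")
        assert new == state

    def test_prediction_replaces_partial_word_with_trailing_space(self, speller):
        state = self._spelling_state(speller, "F")
        preds = speller.predictions(state)
        assert preds[0] == "Francisco"
        state, _ = speller.apply_selection(state, "PRED1")
        assert state.spelled == "Francisco "

    def test_delete_word_removes_whole_last_word(self, speller):
        state = self._spelling_state(speller, "HOLA QUE")
        state, _ = speller.apply_selection(state, "Del. W")
        assert state.spelled == "HOLA "
        state, _ = speller.apply_selection(state, "Del. W")
        assert state.spelled == ""

    def test_empty_prediction_slot_is_a_no_op(self, speller):
        state = self._spelling_state(speller, "ZZZZ")
        new, _ = speller.apply_selection(state, "PRED1")
        assert new == state

    def test_foreign_item_rejected(self, speller):
        with pytest.raises(ValueError):
            speller.apply_selection(speller.initial_state(), "Send WA")

    @staticmethod
    def _spelling_state(speller, spelled):
        prefix = COMMAND_TEMPLATES["Send WA"]
        return SpellerState(menu=MENU_SPELLING, sentence=prefix + spelled,
                            prefix_len=len(prefix))

    @given(st.text(alphabet="ABC0", min_size=0, max_size=6),
           st.sampled_from(list("ABCDEFGHIJ0123456789")))
    @settings(max_examples=50, deadline=None)
    def test_type_then_delete_restores_state(self, spelled, char):
        """Buffer conservation: appending any character and deleting it
        returns the identical state."""
        speller = Speller()
        state = self._spelling_state(speller, spelled)
        typed, _ = speller.apply_selection(state, char)
        back, _ = speller.apply_selection(typed, "Del.")
        assert back == state

    def test_every_menu_reaches_nc(self, speller):
        """Reachability: from any menu a short path leads back to NC."""
        paths = {
            MENU_IC: ["NC"],
            MENU_SPELLING: ["IC", "Confirm", "NC"],
            MENU_CONFIRMATION: ["Back", "IC", "Confirm", "NC"],
        }
        for menu, path in paths.items():
            prefix = COMMAND_TEMPLATES["Send WA"]
            if menu == MENU_IC:
                state = SpellerState(menu=menu)
            elif menu == MENU_SPELLING:
                state = SpellerState(menu=menu, sentence=prefix, prefix_len=len(prefix))
            else:
                state = SpellerState(menu=menu, sentence=prefix,
                                     prefix_len=len(prefix), pending="ok")
            for item in path:
                state, _ = speller.apply_selection(state, item)
            assert state.menu == MENU_NC


class TestPrediction:
    def test_packaged_corpus_serves_the_protocol_availabilities(self):
        corpus = packaged_corpus()
        assert "Francisco" in predict_words(corpus, "F")
        assert "experimento" not in predict_words(corpus, "EX")
        assert "experimento" in predict_words(corpus, "EXP")
        assert "universidad" not in predict_words(corpus, "U")
        assert "universidad" in predict_words(corpus, "UN")
        assert "Ricardo" not in predict_words(corpus, "R")
        assert "Ricardo" in predict_words(corpus, "RI")

    def test_unmatched_prefix_gives_empty_list(self):
        assert predict_words(packaged_corpus(), "QX") == []

    def test_empty_prefix_returns_seven_most_frequent(self):
        corpus = WordCorpus([("B", 5), ("A", 5), ("C", 9)] +
                            [(f"W{i}", 100 + i) for i in range(7)])
        top = predict_words(corpus, "")
        assert len(top) == 7 and all(w.startswith("W") for w in top)

    def test_frequency_ties_break_alphabetically(self):
        corpus = WordCorpus([("BETA", 5), ("ALFA", 5), ("GAMMA", 4)])
        assert predict_words(corpus, "") == ["ALFA", "BETA", "GAMMA"]


def exhaustive_minimum(speller, task, depth_cap=12, buffer_cap=6, alphabet="Z"):
    """Independent oracle: breadth-first search over every cell of every menu
    (deletes and slots included).  To keep the state space enumerable the
    single-character items are limited to the letters of the task payload
    plus a distractor; any other letter is interchangeable with the
    distractor, and no-op dummies never shorten a plan, so the minimum is
    unaffected."""
    letters = {c for stage in task.stages if stage.spelled
               for c in stage.spelled.upper() if c not in " ,"}
    letters |= set(alphabet)
    start = (speller.initial_state(), 0)
    seen = set()
    queue = deque([(start, 0)])
    while queue:
        (state, idx), depth = queue.popleft()
        if depth >= depth_cap:
            continue
        layout = speller.catalog.layout(state.menu)
        items = {layout.grid[r][c] for r in range(7) for c in range(7)}
        items = {i for i in items if len(i) > 1 or not i.isalnum() or i in letters}
        for item in items:
            new, eff = speller.apply_selection(state, item)
            new_idx = idx
            for spoken in eff.spoken:
                from spellersim.speller_fsm import stage_done
                if new_idx < len(task.stages) and stage_done(spoken, task.stages[new_idx]):
                    new_idx += 1
            if new_idx >= len(task.stages):
                return depth + 1
            if len(new.spelled) > buffer_cap:
                continue
            key = (new_idx, new.menu, new.pending, new.sentence[: new.prefix_len],
                   new.spelled.upper())
            if key not in seen:
                seen.add(key)
                queue.append(((new, new_idx), depth + 1))
    raise AssertionError("oracle found no plan within the depth cap")


class TestPlanner:
    def test_task1_requires_exactly_19_actions(self, speller):
        plan = plan_minimum_actions(default_tasks()[1], speller)
        assert len(plan) == 19
        assert plan[:2] == ["IC", "Send WA"] and plan[-2:] == ["OK", "Confirm"]

    def test_task2_requires_exactly_2_actions(self, speller):
        assert plan_minimum_actions(default_tasks()[2], speller) == ["IC", "Read SMS"]

    def test_task3_fixed_part_is_6_actions(self, speller):
        task = TaskSpec(3, (Stage("Read TG", None), Stage("Reply", "")))
        assert len(plan_minimum_actions(task, speller)) == 6

    def test_task4_fixed_part_is_7_actions(self, speller):
        assert len(plan_minimum_actions(task4_fixed_part(), speller)) == 7

    @pytest.mark.parametrize("payload", ["A", "AB", "BEA"])
    def test_planner_matches_exhaustive_search_on_toy_tasks(self, payload):
        corpus = WordCorpus([("BETA", 10), ("ALFA", 8)])
        speller = Speller(corpus=corpus)
        task = TaskSpec(9, (Stage("Send SMS", payload),))
        plan = plan_minimum_actions(task, speller)
        assert len(plan) == exhaustive_minimum(speller, task)

    def test_prediction_shortens_toy_plans(self):
        corpus = WordCorpus([("BETA", 10)])
        speller = Speller(corpus=corpus)
        task = TaskSpec(9, (Stage("Send SMS", "BETA"),))
        plan = plan_minimum_actions(task, speller)
        # BETA sits in the empty-partial slots: IC, Send SMS, slot, OK, Confirm
        assert len(plan) == 5 == exhaustive_minimum(speller, task)
        assert "PRED1" in plan


class TestSimulatedUser:
    def test_wrong_character_triggers_delete(self, speller):
        task = default_tasks()[1]
        prefix = COMMAND_TEMPLATES["Send WA"]
        state = SpellerState(menu=MENU_SPELLING, sentence=prefix + "FX",
                             prefix_len=len(prefix))
        assert simulated_user_policy(state, task, speller) == "Del."

    def test_wrong_word_triggers_delete_word(self, speller):
        task = default_tasks()[1]
        prefix = COMMAND_TEMPLATES["Send WA"]
        state = SpellerState(menu=MENU_SPELLING, sentence=prefix + "Francisco ESTAR ",
                             prefix_len=len(prefix))
        assert simulated_user_policy(state, task, speller) == "Del. W"

    def test_unintended_ic_exit_answered_with_back(self, speller):
        task = default_tasks()[1]
        prefix = COMMAND_TEMPLATES["Send WA"]
        state = SpellerState(menu=MENU_CONFIRMATION, sentence=prefix + "FRA",
                             prefix_len=len(prefix), pending="ic")
        assert simulated_user_policy(state, task, speller) == "Back"

    def test_error_free_run_replays_the_minimum_plan(self, speller):
        task = default_tasks()[1]
        plan = plan_minimum_actions(task, speller)
        state = speller.initial_state()
        executed = []
        for _ in range(25):
            item = simulated_user_policy(state, task, speller)
            if item is None:
                break
            executed.append(item)
            state, _ = speller.apply_selection(state, item)
        assert executed == plan
        assert completed_stages(state.transcript, task) == len(task.stages)
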