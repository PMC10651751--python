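"""Simulate the probabilistic classification task and summarise behavior.

Builds one synthetic session (3 blocks x 160 trials, 90/10 contingency),
lets an agent with 80% optimal responding play it, and prints the per-card
accuracy and reaction-time summary plus the learner classification.
"""

from megfeedback import (TaskConfig, classify_learner, compute_accuracy_rt,
                         generate_task_session, simulate_agent_responses)

session = generate_task_session(TaskConfig(), seed=1, subject_id="demo")
done = simulate_agent_responses(session, target_accuracy=0.8, seed=2)

row = compute_accuracy_rt(done)
print(f"trials completed:        {row['n_trials_completed']}")
print(f"positive-card accuracy:  {row['pos_accuracy']:.3f}")
print(f"negative-card accuracy:  {row['neg_accuracy']:.3f}")
print(f"positive-card mean RT:   {row['pos_rt']:.0f} ms")
print(f"learner (>65% correct):  {classify_learner(row['pos_accuracy'])}")

# The accuracy estimates sit near the agent's 0.8 target (binomial noise on
# ~240 trials per card type); 'learner' is True because 0.8 > 0.65.
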