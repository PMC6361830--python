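# Published default parameter set of the time-cell chain model.
# All quantities are in the model's own unit system (mV, ms); loading an
# empty file resolves to exactly these values.

# --- membrane and D-type potassium current ---
C_m = 200        # membrane capacitance
g_L = 8          # leak conductance
E_L = -65        # leak reversal (mV)
g_D = 4          # D-current maximal conductance
E_K = -90        # potassium reversal (mV)
m_d_tau = 0.6    # D-current activation time constant (ms)
h_d_tau = 1500   # D-current inactivation time constant (ms); 3000 in the chain-wave run
V_T = -50        # spike threshold (mV)
v_R = -85        # reset potential (mV)
v_init = -75     # initial membrane potential (mV)

# --- synapses ---
g_Exc = 15       # feedforward excitatory maximal conductance
g_Excr = 50      # recurrent (within-ensemble) excitatory conductance
E_Exc = 0        # excitatory reversal (mV)
beta = 0.2       # synaptic decay rate (1/ms)
g_Inh = 0.02     # per-activated-cell inhibitory conductance
E_Inh = -100     # inhibitory reversal (mV)

# --- network ---
n_cells = 60
persistent_period = 16   # ms between spikes of a persistently active ensemble
coupling = mean-field    # feedforward output of an active ensemble: mean-field | sawtooth
stall_window = 10000     # ms without a new first spike => wave declared dead
seed = 0

# --- noise ---
sd_gD = 1        # SD of the per-trial g_D draw
sd_gExc = 5      # SD of the per-trial g_Exc draw
draw_mode = per_trial    # conductance draw granularity: per_trial | per_cell
poisson = true   # Poisson synaptic bombardment on/off
n_presyn = 100   # presynaptic units per cell
rate_hz = 50     # rate per presynaptic unit
g_noise = 1      # bombardment maximal conductance (shared across the units)
beta_n = 0.1     # bombardment synaptic decay rate (1/ms)

# --- integration ---
dt = 0.05        # ms
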