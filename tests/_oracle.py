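"""Independent direct-arithmetic oracle for the five ASM equations.

Deliberately standalone: no imports from bia_asm, each equation written out
term by term from the published coefficient listings so the registry-based
evaluator can be checked against it.  Inputs: sex "male"/"female", age yr,
height m, weight kg, resistance Ohm, reactance Ohm.
"""
import math


def sergi(sex, age, height_m, weight, resistance, reactance):
    ri = (height_m * 100.0) ** 2 / resistance
    s = 1.0 if sex == "male" else 0.0
    return -3.964 + 0.227 * ri + 0.095 * weight + 1.384 * s + 0.064 * reactance


def kyle(sex, age, height_m, weight, resistance, reactance):
    ht2_r = (height_m * 100.0) ** 2 / resistance
    s = 1.0 if sex == "male" else 0.0
    return -4.211 + 0.267 * ht2_r + 0.095 * weight + 1.909 * s - 0.012 * age + 0.058 * reactance


def peniche(sex, age, height_m, weight, resistance, reactance):
    ht2_r = (height_m * 100.0) ** 2 / resistance
    s = 1.0 if sex == "male" else 0.0
    return -0.05376 + 0.2394 * ht2_r + 2.708 * s + 0.065 * weight


def kim(sex, age, height_m, weight, resistance, reactance):
    ht2_r = (height_m * 100.0) ** 2 / resistance
    s = 1.0 if sex == "male" else 0.0
    return ht2_r * 0.104 + age * -0.050 + s * 2.954 + weight * 0.055 + 5.663


def yoshida(sex, age, height_m, weight, resistance, reactance, index="z"):
    if index == "z":
        denom = math.sqrt(resistance**2 + reactance**2)
    else:
        denom = resistance
    idx = (height_m * 100.0) ** 2 / denom
    if sex == "male":
        return 0.197 * idx + 0.179 * weight - 0.019
    return 0.221 * idx + 0.117 * weight + 0.881


ALL = {"sergi": sergi, "kyle": kyle, "peniche": peniche, "kim": kim, "yoshida": yoshida}
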