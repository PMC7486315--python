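20.0–50.0 cm tall, erect. Stem pubescent in lower part, scabrous, pubescent with sessile glands in upper part; with 8–12 distinct internodes, the uppermost internode obviously longer than the next upper internode. Basal leaves linear or oblanceolate, pubescent. Cauline leaves linear 10.0–40.0× 1.0–3.0 mm, pubescent. Calyx 25.0–30.0 mm long, ovoid at anthesis and clavate in fruit, pubescent; teeth unequal; shorter ones 2.0–4.0 mm, ovate, acuminate; longer ones 4.0–6.0 mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 10.0–12.0 mm long, glabrous; limbs 7.0–9.0 mm long, bifid, upper-surface pink, lobes oblong, petal limbs cleft to middle or more; coronal scales 2.0–2.2 mm long. Anthophore 13.0–16.0 mm long, glabrous or puberulent. Anthers exserted; filaments 12.0–15.0 mm long, glabrous. Styles exserted. First pedicel 1.0–4.0 cm in flower, 2.0–6.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 12.0 mm long, oblong or ellipsoid. Seeds 0.8–1.0 mm wide.
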