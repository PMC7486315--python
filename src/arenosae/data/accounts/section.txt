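Annuals. Stems erect or ascending, 5–70 cm, often pubescent at least below, internodes often with sessile glands on upper part. Basal leaves lanceolate to oblanceolate, ± covered with unicellular trichomes; cauline leaves linear, lanceolate or oblanceolate, pubescent. Inflorescence an apical, uneven dichasium with long internodes, several later axillary inflorescences from upper stem nodes usually present. Flowers usually nocturnal (e.g. *S. austroiranica*, *S. linearis*), rarely diurnal (*S. exsudans* Boiss. & Heldr., *S. leyseroides*, S. microsperma subsp. cypria Eggens, F.Jafari & Oxelman, nom nov.). Calyx teeth often with distinct mucro, heteromorphic with three longer, often acute, narrowly lanceolate teeth with a narrow transparent margin, the other two teeth shorter, slightly broader, rounded and with a broad transparent margin; margin usually densely ciliate. Primary calyx veins mostly green (or reddish when exposed), often raised; secondary veins obscure; area between veins whitish. Styles 3. Petal limb upper surfaces white or pink. Capsule ellipsoid, oblong or obovate. Seeds reniform, hilum sunken, side flat, with a dorsal groove, testa smooth or papillate.
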