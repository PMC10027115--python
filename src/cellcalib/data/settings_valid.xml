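<?xml version="1.0" encoding="utf-8"?>
<PhysiCell_settings version="sample">
    <!-- fixture settings file: edits must survive round-tripping -->
    <domain>
        <x_min units="micron">-250.0</x_min>
        <y_min units="micron">-250.0</y_min>
        <z_min units="micron">-10</z_min>
        <x_max units="micron">250.0</x_max>
        <y_max units="micron">250.0</y_max>
        <z_max units="micron">10</z_max>
        <dx units="micron">20</dx>
        <dy units="micron">20</dy>
        <dz units="micron">20</dz>
        <use_2D>true</use_2D>
    </domain>
    <overall>
        <max_time units="min">120.0</max_time>
        <time_units>min</time_units>
        <space_units>micron</space_units>
        <dt_diffusion units="min">0.01</dt_diffusion>
        <dt_mechanics units="min">0.1</dt_mechanics>
        <dt_phenotype units="min">6</dt_phenotype>
    </overall>
    <microenvironment_setup>
        <variable name="oxygen" units="mmHg" ID="0">
            <physical_parameter_set>
                <diffusion_coefficient units="micron^2/min">100000.0</diffusion_coefficient>
                <decay_rate units="1/min">0.1</decay_rate>
            </physical_parameter_set>
            <initial_condition units="mmHg">38.0</initial_condition>
            <Dirichlet_boundary_condition units="mmHg" enabled="true">38.0</Dirichlet_boundary_condition>
        </variable>
    </microenvironment_setup>
    <cell_definitions>
        <cell_definition name="default" ID="0">
            <phenotype>
                <cycle code="5" name="live">
                    <phase_transition_rates units="1/min">
                        <rate start_index="0" end_index="0" fixed_duration="false">0.00072</rate>
                    </phase_transition_rates>
                </cycle>
                <death>
                    <model code="100" name="apoptosis">
                        <phase_durations units="min">
                            <duration index="0" fixed_duration="true">516</duration>
                        </phase_durations>
                    </model>
                </death>
                <volume>
                    <total units="micron^3">2494</total>
                    <fluid_fraction units="dimensionless">0.75</fluid_fraction>
                    <nuclear units="micron^3">540</nuclear>
                    <fluid_change_rate units="1/min">0.05</fluid_change_rate>
                    <cytoplasmic_biomass_change_rate units="1/min">0.0045</cytoplasmic_biomass_change_rate>
                    <nuclear_biomass_change_rate units="1/min">0.0055</nuclear_biomass_change_rate>
                    <calcified_fraction units="dimensionless">0.05</calcified_fraction>
                    <calcification_rate units="1/min">0.0042</calcification_rate>
                    <relative_rupture_volume units="dimensionless">2.0</relative_rupture_volume>
                </volume>
                <mechanics>
                    <cell_cell_adhesion_strength units="micron/min">0.4</cell_cell_adhesion_strength>
                    <cell_cell_repulsion_strength units="micron/min">10.0</cell_cell_repulsion_strength>
                    <relative_maximum_adhesion_distance units="dimensionless">1.25</relative_maximum_adhesion_distance>
                </mechanics>
                <motility>
                    <speed units="micron/min">2.0</speed>
                    <persistence_time units="min">1.0</persistence_time>
                    <migration_bias units="dimensionless">0.9</migration_bias>
                    <options>
                        <enabled>true</enabled>
                        <use_2D>true</use_2D>
                        <chemotaxis>
                            <enabled>true</enabled>
                            <substrate>oxygen</substrate>
                            <direction>1</direction>
                        </chemotaxis>
                    </options>
                </motility>
            </phenotype>
            <custom_data>
                <sample units="dimensionless">1.0</sample>
            </custom_data>
        </cell_definition>
    </cell_definitions>
    <user_parameters>
        <random_seed type="int" units="dimensionless">0</random_seed>
        <growth_rate type="double" units="1/min">0.1</growth_rate>
        <carrying_capacity type="double" units="dimensionless">1000.0</carrying_capacity>
        <initial_population type="double" units="dimensionless">10.0</initial_population>
    </user_parameters>
</PhysiCell_settings>
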